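# estclean

**EST cleanup by cDNA terminus pattern analysis.**

Raw Sanger ESTs are single-pass reads of cDNA clone ends. Before they are
usable — or depositable — the cloning scaffold has to be stripped away and the
bona fide insert extracted. Conventional vector/quality trimmers do this
blindly; as a result public EST collections contain reads where the
restriction digestion failed, where two fragments were fused by a palindromic
linker, or where a "5′" read is actually a 3′ read. `estclean` is for anyone
curating legacy Sanger EST collections or building cDNA-library QC pipelines:
it reads the *structure* of each raw read and classifies what actually
happened in the wet lab before deciding what to trim.

## The method

A directionally cloned cDNA (two restriction enzymes, e.g. EcoRI/XhoI, plus a
ligated adapter) leaves a diagnostic arrangement of elements at each end of
the insert. The four canonical **termini** are

| name | layout (read 5′→3′) | marks |
|------|---------------------|-------|
| 5TSS | VF1 + EcoRI + adapter | insert 5′ end, sense strand |
| 3TSS | poly(A) + XhoI + VF2 | insert 3′ end, sense strand |
| 5TNS | VF2′ + XhoI + poly(T) | read 5′ end, antisense strand |
| 3TNS | adapter′ + EcoRI + VF1′ | read 3′ end, antisense strand |

where VF1/VF2 are the vector borders flanking the cloning sites and X′ is the
reverse complement of X. Each family has sub-variants (5TNS-1 … 5TNS-5, …)
for loci where elements are missing or replaced by a single base.

Every detected terminus *t* gets a confidence score

> Conf(t) = w_A·A + w_B·B + w_C·C,  w on the simplex (default ⅓ each)

with **A** = completeness (100 × elements present / elements in the canonical
terminus), **B** = flanking context (100 where the flank matches expectation —
vector upstream of a 5TSS, insert downstream — 50 for low-quality
non-matching content, 0 for confident non-matching content; averaged over
both flanks), and **C** = percentage of terminus bases matching the expected
element sequences.

The read's **pattern** — the ordered token string of terminus names and V/N
(vector/non-vector) context, e.g. `N,3TNS-1,V,3TSS-2` — is matched against
signature templates to classify:

* **RECA** (restriction enzyme cutting abnormality) types A1–F: an enzyme
  failed to cut, cut at the wrong site, or the excised stuffer was re-ligated
  with (possibly inverted) inserts. These reads are filtered.
* **DBT** (double-termini adapter): the palindromic concatenations
  `CCTCGTGCC+G+AATTC+GGCACGAGG` (type 1) and `AATTC+GGCACGAGG+CCTCGTGCC+G`
  (type 2) that can fuse two fragments into a chimera. A DBT strictly inside
  a valid 5TNS…3TNS span of a 3′ read is excised; any other DBT filters the
  read.
* **CASE 1–8**: the frequent simple abnormal patterns (lone poly(A)
  fragments, single-base enzyme-site replacements, bare vector borders,
  direction conflicts).

Clean reads are trimmed via the best **reasonable pair**: a
direction-consistent (5′-family, 3′-family) terminus pair, in order, ≥200
bases apart, maximizing cumulative confidence; the span between the inner
edges is then shrunk past vector hits and low-quality segments.

## Worked example

```python
import numpy as np
from estclean import default_protocol, process_read
from estclean.simulate import ConstructRecipe, make_construct
from estclean.elements import ReadRecord

protocol = default_protocol()
rng = np.random.default_rng(7)
bases, truth = make_construct(
    ConstructRecipe("expected-3", "demo.b1", insert_length=400), protocol, rng)
report = process_read(ReadRecord("demo.b1", bases, designated_direction="3"),
                      protocol)
print(report.pattern_rendering, report.primary_category, report.outcome)
print(report.clean_interval, truth.clean_interval)
```

prints

```
pattern: 5TNS,N,3TNS
category: expected | outcome: clean
clean interval (1-based): 75 - 474
truth insert: 75 - 474
  5TNS: [1-74] A=100.0 B=100.0 C=100.0 conf=100.0
  3TNS: [475-539] A=100.0 B=100.0 C=100.0 conf=100.0
```

— a normal 3′ read: both canonical antisense termini found at full
confidence, and the 400-base insert between their inner edges recovered
exactly at the planted coordinates.

From the shell, the same pipeline over a simulated dataset:

```bash
estclean simulate -n 24 --seed 5 --out-dir demo \
  --proportions "expected-5=0.3,expected-3=0.3,RECA-A1-5=0.1,RECA-C-5=0.1,DBT-internal=0.1,CASE-1=0.1"
estclean trim demo/reads.fasta --qual demo/reads.qual --out-dir demo_out
# 20 clean inserts -> demo_out/clean.fasta
# 24 reads, 24 with termini (100.0%), 20 clean, 4 filtered
```

The RECA reads are the 4 filtered ones; internal-DBT reads come out clean
with the linker excised; `demo_out/report.tsv` holds one row per read with
its pattern, calls, sub-scores and 1-based clean coordinates.

Real data goes through the same commands: supply your reads as FASTA (+
optional QUAL) and your library protocol as a small YAML (vector sequence,
VF1/VF2 coordinates, enzyme motifs, adapter, read-naming direction rules)
via `--protocol`.

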