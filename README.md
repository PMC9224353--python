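# demism

Fuzzy DEMATEL → MMDE → ISM → MICMAC: a hybrid multi-criteria decision
pipeline for untangling *which factors drive which* in a complex system,
from nothing more than a panel of expert judgments.

Safety analysts, risk managers and decision scientists often face a web
of 10–30 interacting factors — say, the influences on miners' unsafe
behaviors in highly automated coal mines — and a handful of experts who
can only rate pairwise influence on a coarse linguistic scale ("no / very
low / low / high / very high"). `demism` turns such a panel into:

1. **a crisp direct-influence matrix** — each linguistic rating becomes a
   triangular fuzzy number (l, m, r) and the CFCS method ("converting
   fuzzy data into crisp scores") collapses the k experts' TFNs per cell
   into one crisp value;
2. **a total relation matrix** (DEMATEL) — T = N(I − N)⁻¹ accumulates
   direct and indirect influence; row sums D_i and column sums R_i give
   each factor's centrality D_i + R_i and causality D_i − R_i;
3. **an objective edge threshold** (MMDE, maximum mean de-entropy) — the
   n² entries of T are ordered descending, and the prefix of the source /
   target node sequences maximizing (ln m − H_emp)/m (m distinct nodes,
   empirical entropy H_emp) isolates the dominant dispatchers and
   receivers; the threshold λ is the weakest of their strongest links, so
   no analyst judgment call is needed to draw the digraph;
4. **a causal hierarchy** (ISM) — T is binarized at λ, closed
   transitively, and partitioned into levels from the directly-affected
   surface layer down to root causes;
5. **a four-quadrant classification** (MICMAC) — factors are placed by
   driving power (reachability row sum) vs dependence (column sum) into
   autonomous / dependent / linkage / driving clusters.

Every stage is exposed as a plain function on pandas DataFrames, and as a
CLI subcommand that reads/writes labeled CSV so stages can be chained or
entered midway (from an existing direct matrix or total relation matrix).
A synthetic-panel generator with plantable "driver" factors makes the
whole chain testable end to end.

## Worked example

The package bundles its reference dataset: a 20-factor study of the
influences on miners' unsafe behaviors in intelligent mines (factors
x1..x20 spanning individual, device, management and environment
dimensions), as the 20×20 total relation matrix of a seven-expert fuzzy
DEMATEL elicitation.

```python
from demism import load_miner_safety, run_pipeline

report = run_pipeline(total=load_miner_safety())
print(report.threshold)          # 0.2463
print(report.ism.to_dict())
print(report.micmac.to_dict()["clusters"])
```

or from the shell:

```console
$ demism run --total total.csv -o report
threshold 0.2463
level 1: x1 x2 x3 x4 x5 x6 x7 x8 x9 x10 x14 x15 x16 x17 x18 x20
level 2: x11 x12 x13
level 3: x19
report -> report
```

Reading the output: the MMDE threshold 0.2463 keeps exactly ten
influences. Government regulation (x19) is the sole deepest factor — a
root cause acting through the intermediate management levers: leadership
attention (x11), safety-system standardization (x12) and safety input
level (x13). The remaining sixteen factors form the surface layer that
is acted upon directly. The MICMAC table (`report/micmac.csv`) agrees
from the other direction:

```text
factor,driving,dependence,quadrant,cluster
x8,1,3,II,dependent
x11,4,1,IV,driving
x13,4,1,IV,driving
x15,1,5,II,dependent
x18,1,3,II,dependent
x19,4,1,IV,driving
...
```

x11, x13 and x19 are the driving cluster (high driving power, low
dependence — the levers to manage first), while device safety status
(x8), emergency management capability (x15) and organizational safety
culture (x18) are the dependent cluster — outcomes to monitor, shaped by
the levers. The DEMATEL scores in `report/scores.csv` add the magnitude
view: x18 has the highest centrality D+R ≈ 7.51, x19 the highest
causality D−R ≈ 2.18.

Synthetic data for experimentation:

```console
$ demism simulate --n 20 --experts 7 --seed 1 --drivers 1,2 -o panel/
$ demism run --manifest panel/manifest.yaml -o synth_report/
```

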