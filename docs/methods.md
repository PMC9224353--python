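# Methods

`demism` implements a hybrid multi-criteria decision pipeline for group
influence analysis: fuzzy DEMATEL with CFCS defuzzification, maximum mean
de-entropy (MMDE) threshold selection, interpretive structural modelling
(ISM), and MICMAC classification. This note records the model, the
numerical choices, and the places where the method as commonly printed is
ambiguous and the package had to commit to a reading.

## Input model

A panel of k experts each rates the direct influence of factor i on
factor j on a five-term linguistic scale. Each term maps to a triangular
fuzzy number (TFN) (l, m, r), l ≤ m ≤ r, on [0, 1]:

| term | meaning              | (l, m, r)        |
|------|----------------------|------------------|
| No   | no influence         | (0, 0, 0.25)     |
| VL   | very low influence   | (0, 0.25, 0.5)   |
| L    | low influence        | (0.25, 0.5, 0.75)|
| H    | high influence       | (0.5, 0.75, 1.0) |
| VH   | very high influence  | (0.75, 1.0, 1.0) |

The scale is validated to be component-wise monotone, which is what makes
the CFCS crisp value monotone in the term ordinal (checked exhaustively in
the tests). Diagonal cells are recorded as "No" — a factor is not rated
against itself — and flow through defuzzification like any other cell; the
`zero_diagonal` option instead forces the crisp diagonal to exactly 0 for
users who prefer the stricter convention. Both conventions appear in
practice; the default keeps the recorded judgment, and every published
quantity the package reproduces is computed downstream of the total
relation matrix, where the choice is immaterial.

## CFCS defuzzification

Per cell (i, j), with Δ = max_k r − min_k l over the k experts:

1. standardize each expert's TFN into [0, 1] by (· − min l)/Δ;
2. left and right normalized scores
   xls = xm/(1 + xm − xl), xrs = xr/(1 + xr − xm);
3. crisp normalized score x = [xls(1 − xls) + xrs²]/[1 − xls + xrs];
4. rescale z_k = min l + x·Δ and average over experts.

The min/max defining Δ are taken per cell across experts (the published
CFCS convention), not globally. When Δ = 0 — every expert gives the same
degenerate point TFN — the cell takes that common value, the continuous
limit of the formulas; the vectorized implementation guards the division.
Single-rating anchor values: H → 0.75 exactly, No → 1/24 ≈ 0.0417.

## DEMATEL

The crisp direct matrix D is normalized by
s = max(max row sum, max column sum), and the total relation matrix is
T = N(I − N)⁻¹, computed by a linear solve (never a truncated power
series; a truncated-series brute force serves as test oracle). The solve
refuses when cond(I − N) > 1e12 — this happens exactly when the
normalized matrix cannot converge, e.g. a symmetric 2×2 system where
every row sum ties the maximum. Row sums D_i of T measure dispatched
influence, column sums R_i received influence; D+R is centrality, D−R
causality (positive = net cause). Comparisons against 4-decimal published
tables use 5e-3 absolute tolerance, since such tables are printed rounded
but summed unrounded.

## MMDE threshold

All n² entries of T are sorted descending (ties broken by row then column
index — no ties occur in the bundled fixture) into triplets
(t_ij, source, target). For a prefix of length t of the source
("dispatch") or target ("receive") node sequence, with m distinct nodes
of occurrence counts k_u:

    MDE_t = (ln m − H_emp) / m,  H_emp = −Σ_u (k_u/t) ln(k_u/t).

This is the information gained relative to a uniform spread over the
prefix's own m nodes, averaged per node; natural logarithm throughout.
The printed forms of this statistic circulating in the literature are
not computable as written (the reference distribution and denominator
mix whole-sequence and prefix quantities); the reading above is the one
that reproduces all published intermediate curve values we can check
(0.0283, 0.0196, 0.0146 on the dispatch side; 0.0101 on the receive
side of the bundled fixture).

**Prefix scan range.** The scan is capped at t ≤ n (the factor count) by
default; `prefix_limit` overrides it, up to n². The cap is deliberate.
The statistic is meant to isolate a *small* dominant node set from the
head of the ordering; scanned over all n² prefixes its maximum can drift
deep into the sequence where large, diffuse node sets score high. On the
bundled 20-factor fixture the two ranges disagree: capped, the dispatch
maximum is 0.0367 at t = 14 with node set {x19, x11, x13, x12} and the
receive maximum 0.0291 at t = 6 with {x15, x18, x8}, giving threshold
0.2463 — matching the published node sets, threshold, hierarchy and
classification of the underlying case study exactly; uncapped, the
dispatch maximum is 0.0431 at t = 32 with a six-node set and the
threshold drops to 0.2306, reproducing none of them. The published
dispatch maximum *value* (0.0454) is not attainable from the 4-decimal
printed matrix under either range: it corresponds exactly to prefix
counts (6, 4, 2, 1) at t = 13, an ordering the rounded matrix cannot
produce (its t = 13 counts are (5, 4, 3, 1)); the original analysis
evidently ran on unrounded values whose mid-rank ordering differs. The
package therefore reproduces the maximizing node sets and everything
downstream, and reports its own computed maxima.

Ties at the curve maximum resolve to the earliest prefix, implemented
with a 1e-12 tolerance because exact mathematical ties between different
prefix lengths exist (count patterns (2,1) and (2,2,1,4) both give
(5/6)ln2 − (1/2)ln3) and incremental-entropy float noise must not flip
them.

For each node in the dispatch-side maximizing set the first (largest)
triplet with that source, and for each receive-side node the first with
that target, enter the threshold set; the threshold λ is its minimum
value, hence always an actual entry of T.

## ISM

H_ij = 1 iff t_ij ≥ λ — the comparison is inclusive; in the fixture the
weakest retained influence (x12 → x15) sits exactly at λ. K is the
reflexive-transitive Warshall closure of H. Levels are extracted
iteratively on the remaining submatrix: the surface level is
{s : R(s) ∩ A(s) = R(s)} (everything s still reaches already feeds back
to it); level 1 is the surface layer, the highest index the deepest
cause. The alternative root-first extraction {R ∩ A = A} is exposed as
`rule="root"`. The two rules are *not* mirror images on general
matrices: factors isolated after thresholding satisfy both conditions
and always surface in round one, so on the fixture the root rule yields
a different (equally valid, bottom-up) stratification rather than the
reversed one. Transitive influence is handled entirely by the closure;
no additional edge pruning is applied to the thresholded digraph.

## MICMAC

Driving power = row sum of K, dependence = column sum (both include the
reflexive self-loop, so each lies in [1, n] and the two totals are equal
by construction). Axis boundaries default to the midpoint of each axis's
observed min–max range, with counts equal to the boundary classified as
"high"; quadrants are I autonomous (low/low), II dependent, III linkage,
IV driving. The midpoint rule is the one consistent with the published
classification of the bundled fixture (dependence 3 must count as high,
driving 2 as low); the common n/2 alternative misclassifies nearly every
factor there. Boundaries are user-overridable. A degenerate axis (all
counts equal) classifies everything low on that axis and warns.

## Synthetic panels

The generator emulates a multi-expert linguistic elicitation: each
expert's off-diagonal cells are drawn iid from a base distribution over
the five terms — default (0.15, 0.25, 0.30, 0.20, 0.10) for
(No, VL, L, H, VH), a mostly weak-to-moderate survey profile — with
k = 7 experts and n = 20 factors by default, matching a typical
five-to-seven member decision panel. Planted "driver" factors have all
outgoing ratings shifted up the ordinal scale (default 2 steps — a
strong, unambiguous effect), "sinks" their incoming ratings; each expert
then independently perturbs each cell by ±1 term with probability 0.1.
Shifts clamp at the scale ends and the diagonal is forced to "No".
Everything derives from a single `numpy` generator seed.

What the generator does *not* emulate: correlated expert opinion,
block structure among factor dimensions, systematic rater severity, or
any attempt to match a particular real panel's response distribution.
Passing the recovery tests therefore shows the pipeline can detect
strongly planted asymmetric influence under iid noise — not that it
would resolve subtler structure in real survey data.

End-to-end sanity: over 100 seeds, two factors with outgoing ratings
lifted two terms are recovered in the driving cluster (or as the top two
by driving power) in ≥ 90% of runs, and top the D−R causality ranking;
with no planted shift, recovery is at chance. These Monte-Carlo sizes
(100 panels of 20 factors × 7 experts) keep the full suite under a few
seconds while leaving no statistical ambiguity at the 90% bound.

## Known limitations

- No expert weighting: all experts enter the CFCS average equally.
- No interval type-II fuzzy sets; the scale is fixed five-term triangular
  (overridable TFNs per term via the manifest).
- The MMDE prefix-range ambiguity above means thresholds from other
  implementations may differ on matrices where the capped and full scans
  disagree; `prefix_limit` reproduces either convention.
- MICMAC boundaries are a convention, not an estimate; sensitivity to
  them should be checked when counts cluster near the midpoint.
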