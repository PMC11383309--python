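# Methods

This note documents the models and procedures implemented in receptorkit,
the defaults that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Pull-down quantification pipeline

The pipeline order is fixed: quantifiability filter → log2 transform →
mode normalization → MNAR imputation → enrichment. Normalization is computed
on and applied to observed values only; imputation happens strictly
afterwards, on the normalized matrix.

### Quantifiability filter

Rows are kept when they are non-contaminant and have at least
`min_peptides` (default 2) unique peptides. Contaminants are identified by a
boolean column when the input provides one, otherwise by protein-id prefix
(default `contam_`). Zero and empty intensity cells are recorded as missing:
an LFQ value of 0 means non-detection, and treating it as log2(0) = −∞ would
poison every downstream statistic. The filter is idempotent and an empty
result is legal (warning, not error).

### Mode normalization

For samples *i, j*, the mode of {x<sub>pi</sub> − x<sub>pj</sub>} over
jointly observed proteins *p* estimates the systematic log2 offset between
the samples. Mode estimation: Gaussian KDE with Silverman bandwidth
evaluated on a 512-point grid spanning [min − bw, max + bw]; the mode is the
grid argmax, with ties broken toward the value closest to 0 (conservative
normalization). Below 100 shared observations the estimator falls back to a
Freedman–Diaconis histogram argmax. Pairs must share at least `min_shared`
(default 30) observations; fewer is an error naming the pair.

Factor reconciliation is zero-sum least squares over all pairs. For any
antisymmetric mode matrix the normal equations collapse to row means,
f<sub>i</sub> = (1/n) Σ<sub>j</sub> m<sub>ij</sub>, so the closed form is
used directly; `residual_rms` is the root-mean-square of
f<sub>i</sub> − f<sub>j</sub> − m<sub>ij</sub> over pairs and reports how
inconsistent the pairwise modes were. This scheme uses every pair
symmetrically and needs no arbitrary reference sample.

Why the mode: means and medians of pairwise ratios shift when a sizeable
minority of proteins is genuinely differential (heavy spiking in one group);
the mode tracks the unchanged majority. The per-pair KDE mode estimate
itself carries sampling jitter of roughly ±0.03 log2 (sd) at ~1500 shared
proteins; the reconciliation averages this over n−1 pairs per sample, which
is why factor recovery (±0.05) is tighter than any single pairwise mode.

`ModeNormalizer` exposes this as a scikit-learn transformer (columns =
samples, rows = proteins, NaN = missing): `fit` learns `factors_`,
`transform` subtracts them.

### Imputation

Per sample *s*: μ<sub>s</sub> = median − 1.8·sd, σ<sub>s</sub> = 0.3·sd of
the sample's observed log2 intensities, with the sample (n−1) standard
deviation — at proteome scale the n vs n−1 distinction is negligible, and
the sample sd is the convention of the surrounding workflow. Each missing
cell receives an independent Normal(μ<sub>s</sub>, σ<sub>s</sub>) draw.
σ = 0 (a constant sample) legally degenerates to deterministic imputation at
μ. A sample with fewer than two observed values is an error.

Randomness: one `numpy.random.default_rng(seed)` (PCG64) stream per run,
consuming one standard-normal deviate per matrix cell in row-major
(protein, sample) order; a fixed seed reproduces the imputed matrix bit for
bit, and the run manifest records the generator name.

### Enrichment

Per protein: log2fc = mean(bait) − mean(control) on the complete (imputed)
matrix; two-sample t-test; two-sided p; BH q-values over all tested
proteins; primary ranking by log2fc descending with ties broken by smaller
p, then protein id.

The default statistic is the pooled-variance Student t (df = n1 + n2 − 2).
At the 2–3 replicates typical of pull-downs the Welch test is intrinsically
conservative — its measured type-I rate at the 0.05 level is ≈ 0.034 for 3v3
normal data — while the pooled t is exact when both groups share the same
measurement noise, as they do for replicate injections of the same workflow.
Welch (with Welch–Satterthwaite df) remains available via
`equal_var=False`. Degenerate rows with zero variance in both groups get
t = 0 / p = 1 when the means agree and t = ±∞ / p = 0 otherwise.

Proteins never observed in any sample of the two compared groups are flagged
`fully_imputed` and excluded from `top_hits` by default — their fold change
is a difference of two imputation draws, i.e. pure noise.

**Known limitation — detection-boundary artifacts.** Under
missing-not-at-random dropout, proteins near the detection limit that happen
to be observed in one group and imputed (≈ 1.8 sd below the median) in the
other acquire apparent fold changes of roughly the distance between the
observed values and μ — up to ~2.5 log2 under the default synthetic
conditions. These rows have large within-group variance, so the q-value
threshold in `top_hits` removes them, but they do crowd a ranking that is by
fold change alone. This is a faithful property of down-shifted-Gaussian
imputation on MNAR data, not an implementation artifact; practitioners
commonly add minimum-valid-value filters to suppress it, which this package
deliberately does not impose silently.

## Interface metrics

All metrics consume a `Trajectory` (fixed topology, frames in Å, times in
ns) and are evaluated per frame. No periodic-boundary handling: inputs are
expected to be whole, unwrapped molecules. Residue numbering is taken
verbatim from the topology; no renumbering is applied.

* **Backbone h-bond count** between residue ranges (defaults A:35–39 ↔
  B:129–134): donors are backbone amide N of one range, acceptors backbone
  carbonyl O of the other, both directions, each (N, O) pair counted at most
  once. Criterion: N···O ≤ 3.5 Å, plus N–H···O ≥ 150° when the donor's amide
  hydrogen exists in the topology (distance-only otherwise). The cutoffs are
  the de-facto convention and both are exposed, since upstream tools differ;
  the count is monotone in both cutoffs by construction.
* **Insertion depth** (default probe A:36, anchor B:119:CA): minimum over
  the probe residue's heavy atoms of the distance to the single anchor atom.
  All heavy atoms of the probe residue participate, backbone included.
* **Pocket distance** (default B:133 ↔ B:169): minimum cross-pair distance
  over sidechain heavy atoms, where sidechain = heavy atoms not named
  N, CA, C, O or OXT (CB included). A residue without sidechain heavy atoms
  (glycine) is an error.

Series sampling uses the frame nearest each multiple of `stride_ns`
(default 1 ns) — nearest-frame, never interpolation, because the metrics are
nonlinear in the coordinates. A stride finer than the native spacing warns
and uses every frame.

Multi-MODEL PDB is the trajectory carrier; parsing goes through Biopython
with cross-model atom-count validation on top, elements are taken from
columns 77–78 when present and inferred from atom names otherwise, and
coordinates round-trip at the format's 0.001 Å precision.

## Screen classification

A score table (receptor, optional UniProt id, ipTM, oligomeric state) is
ranked by ipTM descending (ties alphabetical). The hit rule is strict:
ipTM > threshold (default 0.5); a score of exactly 0.5 is not a hit.
Records within ±0.05 of the threshold are annotated `borderline` — an
annotation for follow-up prioritization, never a hit. The module never
invokes structure prediction; inference is GPU-scale and out of scope.

## Synthetic data generators

### LFQ pull-down (`generate_lfq_dataset`)

Cell model in log2: value = baseline<sub>p</sub> + factor<sub>s</sub> +
spike + noise, with baseline ~ N(26, 2.5), per-sample factors uniform in
±1.5 centered to zero sum, replicate noise sd 0.25, and spike = +2 log2 for
the 20 spiked proteins in bait-group samples only. A cell is masked missing
with probability 1/(1 + exp(steepness·(x − midpoint))) (midpoint 22,
steepness 1) — the simplest mechanism consistent with imputing from a
low-shifted Gaussian, and steepness 0 degenerates to MCAR for stress tests.
Spiked proteins are therefore preferentially absent in control samples when
their baseline is low, mimicking real "detected only in bait" hits.
Contaminant (2%) and single-peptide (5%) rows are drawn from within
`n_proteins`, so the filter retains n·(1 − 0.02 − 0.05) rows. Intensities
are emitted as 2^x on the linear scale; the ground truth (true factors,
spiked ids, complete pre-mask matrix) is returned alongside.

What this does not emulate: correlated protein abundances, peptide-level
effects (shared peptides, protein-group ambiguity), batch structure beyond
a scalar per-sample shift, and heavy-tailed measurement noise. Tests passing
on this generator therefore demonstrate correctness of the algorithms under
their stated model, not robustness to every pathology of real LFQ data.

### Toy trajectory (`generate_toy_trajectory`)

A 5-residue LIR-like peptide (residues 35–39; residue 36 carries a
10-heavy-atom tryptophan-like sidechain) above a propeller stub (backbone
residues 129–134, Ile sidechain on 133, Phe-like pocket residue 169, Cα
anchor residue 119). Bound frames hold exactly three backbone h-bonds with
colinear N–H···O at 2.9 Å, the probe sidechain ~3.4 Å from the anchor, and
pocket residues ~6.7 Å apart; unbound frames rigid-shift the peptide by
`displacement` (15 Å). Frames before `switch_frame` are bound, the rest
unbound; Gaussian jitter (sd 0.05 Å) is added to every coordinate.

Every constructed geometry sits at least 6 jitter-sd away from each
criterion boundary (nearest non-bonded N···O pair 4.9 Å vs the 3.5 Å cutoff;
bonded pairs 0.6 Å inside it; colinear angles ~30° inside the 150° cutoff),
so expected h-bond counts are exact with overwhelming probability and
expected distances — computed from the jitter-free construction — hold
within a 6·jitter_sd band. The geometry is a metric test-bed, not
stereochemistry: bond lengths and backbone torsions are approximate.

## Problem sizes and tolerances

The test suite and acceptance script use the generators' default sizes
(2000 proteins × 6 samples; 20-frame, 84-atom trajectories), 50 seeds for
null calibration, 10,000 imputed cells per sample for distributional checks,
and 50–100 random ≤500-atom frames for oracle comparisons. Distance metrics
are compared to exhaustive double-loop enumeration at 1e-9 Å; h-bond counts
must match exactly; KDE-based mode recovery is held to ±0.05 log2 and
factor robustness under 10% +4-log2 spiking to ±0.1 log2. Floating-point
determinism (byte-identical reruns) is asserted for imputation and for the
whole `run-all` output tree; manifests deliberately contain no timestamps.

## Design choices where the design was open

* Mode estimator: KDE + grid argmax rather than histogram argmax at scale —
  smooth, deterministic, resolution-bounded; the histogram fallback covers
  small-n pairs where KDE bandwidths are unreliable.
* Tie-breaks everywhere favor the conservative option (mode closest to 0,
  smaller p, lexicographic ids) so output orderings are total and stable.
* The h-bond criterion and its hydrogen-dependence are explicit parameters,
  not claims about what any particular upstream trajectory tool used.
* "Minimum of two peptides" is read as unique peptides per protein group;
  the column is configurable per input dialect.
* The statistic default (pooled t over Welch) is argued above; both are
  implemented and tested.
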