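# Methods

This note documents the models implemented in `metalrisk`, the defaults and
their units, the numerical choices, and the limits of what the synthetic
data can demonstrate.

## Data model

The primary inputs are per-(species, metal) summary statistics — mean, SD,
minimum and maximum concentration in mg/kg dry weight — for 15 vegetable
and 11 fish species over As, Mn, Cu, Ni, Pb and Cr, bundled as long-format
CSVs. Validation enforces non-negativity and min ≤ mean ≤ max with a 1%
relative slack, because published means are rounded to two decimals.
Concentrations are used as tabulated, with no wet-weight conversion: the
downstream exposure tables reproduce directly from the dry-weight means,
so none was applied upstream of them.

Reference values live in one YAML file: MAC and MTDI per (food class,
metal) — both differ between vegetables and fish, and some entries are
absent (no vegetable MAC or fish MTDI for Mn) — RfD per metal, CSF for the
carcinogens As (1.5) and Pb (8.5E-03) per (mg/kg/day)⁻¹, intake rates
170.04 g/day (vegetables) and 59.91 g/day (fish), body weight 60 kg,
exposure frequency 365 days/year, exposure duration 70 years, averaging
time 25,550 days. Detection limits default to 0.0003 mg/kg for As; the
other metals fall in the instrument's 0.013–0.070 mg/kg window and are
set once per metal inside it (Mn/Cu 0.013, Pb 0.028, Cr 0.05, Ni 0.07),
all configurable.

## Pollution load index

APLI for a species is the mean of Cᵢ/Sᵢ over the usable-MAC metal subset.
Mn is excluded for both food classes: vegetables have no Mn MAC, and for
fish, including the tabulated Mn MAC of 1.0 is numerically inconsistent
with the published index values (e.g. Indian Tilapia would score 6.35
rather than the published 2.31), so the five-metal subset is the default
and the subset is configurable. Category bins are left-closed:
[0, 0.1) unpolluted, [0.1, 0.2) micro, [0.2, 0.5) lightly, [0.5, 0.7)
moderately, [0.7, 1.0) heavily, ≥ 1.0 seriously polluted; a boundary value
belongs to the upper bin.

## Exposure and risk

EDI = FIR·10⁻³·C/BW; THQ = C·FIR·EF·ED·10⁻³/(BW·AT·RfD);
TCR = C·FIR·EF·ED·CSF·10⁻³/(BW·AT). The 10⁻³ converts the intake rate
from g to kg. Under the defaults (EF = 365, AT = 365·ED) THQ = EDI/RfD
and TCR = EDI·CSF exactly; this identity is property-tested. HI sums THQ
over the six metals; TTCR sums TCR over As and Pb. TCR bands are
half-open with the boundary in the upper band (very low < 1E-06 ≤ low <
1E-05 ≤ medium < 1E-04 ≤ high < 1E-03 ≤ very high). The MTDI screen
compares EDI column totals against the MTDI row as tabulated in the
source material.

Reproduction tolerance for table cells is ±3% relative: the published
tables were computed from unrounded means, and a mean printed with two
significant digits introduces up to ~2–3% of rounding error. Cells whose
printed mean has only one significant digit (e.g. a Pb mean of 0.09) can
carry rounding error above 3% and are not used as pinned checks.

## Monte Carlo risk and sensitivity

Each trial evaluates the TCR formula on an independent joint draw of
(C, FIR, EF, ED, BW, AT, CSF). Supported marginals: point, normal,
lognormal (parameterised by arithmetic mean/SD), uniform, triangular, and
empirical (resampling a value set). The default configuration samples C
empirically over the per-species means of the food class, gives FIR, EF,
ED, BW and AT uniform ±20% bands around their defaults, and keeps CSF a
point mass. AT varies independently of ED by default because the
sensitivity surface treats them as separate inputs with opposite signs; a
linked mode (AT = 365·ED) is available. Percentiles use the empirical
quantile with linear interpolation.

Sensitivity follows the contribution-to-variance convention of commercial
risk software: sign(ρᵥ)·100·ρᵥ²/Σρ² with ρᵥ the Spearman rank correlation
between an input's draws and the output draws; point-mass inputs get 0,
and absolute contributions sum to 100. With the default configuration the
concentration dominates (it is by far the widest input), and the expected
sign structure holds: C, FIR, EF, ED positive; BW, AT negative. Only the
sign structure and the single-input ±100% limits are asserted; the exact
percentage split depends on the (unpublished) input distributions.

## PMF receptor model

Uncertainties: α = (5/6)·MDL where the raw value is at or below the MDL
(the condition uses the pre-substitution value), else α = 0.05·X + MDL.
Censored values are replaced by MDL/2 for modelling — the usual receptor-
modelling substitution — with raw values kept for audit.

The solver minimises Q = Σ((X−GF)/α)² by alternating multiplicative
weighted non-negative updates, 20 random starts by default (uniform
initialisation scaled to the data magnitude, seeds derived from the base
seed), keeping the run with the lowest robust Q. A run stops when the
relative objective change falls below 1e-8 or at the iteration cap
(default 5000); hitting the cap is an accepted stop — over-specified
factor counts approach their optimum asymptotically — and the fit fails
only if no start reaches a finite objective. Robust mode applies IRLS
down-weighting: cells with |e/α| > 4 get their effective uncertainty
inflated so the scaled residual becomes √(4·|e/α|), giving
Q_robust = Σ min(r², 4|r|) ≤ Q_true.

Because the survey's raw sample matrices are unpublished, the published
factor percentages are not reproducible from first principles; recovery is
demonstrated on synthetic factor-structured data instead. Identifiability
matters here: with nearly flat contribution columns the weighted-NMF
optimum is rotationally ambiguous and per-metal mass attribution is not
recoverable even when profile cosines exceed 0.95. The recovery tests
therefore use the standard separability condition — contributions with
many source-dominated samples (squared-uniform draws) and profiles with
distinct dominant metals — under which profiles and a known 80%
single-factor attribution are recovered to within a few points at 5%
multiplicative noise.

## Self-organizing map

Node count follows the m = 5·√n heuristic, with the grid chosen as the
integer factor pair closest to m with aspect ratio ≤ 2 (ties go to the
wider grid). Training is the deterministic batch algorithm on column
z-scores: Gaussian neighbourhood, radius decaying linearly from
max(rows, cols)/2 to 1, 500 epochs by default, codebook initialised from
random data rows with a per-node scalar jitter (which keeps duplicated or
permuted columns exactly equivalent). Component planes are codebook
columns reshaped to the grid; plane association is summarised by Pearson
correlations between flattened planes. Because the final neighbourhood
radius stays at 1 (a smoothing regime), the trained quantization error is
compared against a random-codebook baseline, not against the
data-sampled initialisation.

## Multivariate statistics

All four analyses run on the species-mean matrix (15×6 or 11×6).
Bartlett: χ² = −(n−1−(2p+5)/6)·ln|R|, df = p(p−1)/2. KMO: Σr²/(Σr²+Σq²)
over off-diagonal entries, with q the anti-image partial correlations from
the inverse correlation matrix. PCA is an eigendecomposition of the
correlation matrix; retention uses eigenvalue > 1, salience |loading| >
0.5, and each component's sign is fixed so its largest-magnitude loading
is positive; no rotation is applied by default. Clustering targets the
metals: Ward linkage on Euclidean distances between z-scored variable
profiles, which reproduces the As–Mn–Cu / Pb–Cr / Ni grouping for
vegetables and As–Mn–Cr / Cu–Ni / Pb for fish.

## Synthetic samples from summaries

The per-species generator draws from a normal truncated to the published
[min, max], with the parent (μ, σ) solved numerically so the
*post-truncation* mean and SD match the published values — the published
statistics describe the observed samples, not a latent parent. Published
SDs that exceed what any truncated normal can attain on the given range
(a handful of fish cells) are matched as closely as possible; the mean is
still honoured. A truncated-lognormal variant covers right-skewed cells.
sd = 0 with a non-degenerate range yields constant output with a warning.
The generator does not emulate the unknown within-species correlation
between metals; synthetic matrices are suitable for testing the
mechanics and identifiability of the receptor models, not for inferring
the survey's true source structure.

## Pipeline

`run_all` executes tables → indices → risk → Monte Carlo → PMF/SOM (on
synthetic samples regenerated from the summaries, 5 per species by
default, matching the survey's sampling depth) → multivariate, with one
seed per stochastic stage recorded in the JSON report alongside input
hashes; identical configuration gives a byte-identical report. Default
problem sizes (10,000 Monte Carlo trials, 20 PMF starts, 200 SOM epochs
in the pipeline) keep a full run under a minute on one core.
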