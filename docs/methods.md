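# Methods

This note documents the models, algorithms and numerical choices behind
`phylograd`, and what the synthetic studies its tests rely on do and do not
establish about real data.

## Phylogeny preparation

Trees are rooted, with branch lengths (Myr for dated trees) and
`Genus_species` tip labels; matching is exact after trimming whitespace and
replacing spaces with underscores (case-sensitive — no synonym or fuzzy
matching). Pruning retains the induced subtree on the requested tips,
collapsing unifurcations with branch lengths summed, and never changes
patristic distances among retained tips (tested to 1e-9 on random trees).

Species recorded in the field but absent from the tree are grafted
congenerically, in sorted-name order so output is deterministic:

- ≥ 2 congeners: attach at the genus MRCA with a pendant branch equal to the
  MRCA's height above the tips — on an ultrametric tree the new tip is
  contemporaneous with the others;
- exactly 1 congener: bisect its terminal branch at half its length and
  attach a pendant of the same half-length;
- no congeners: exclude and report. How a real study handled such species is
  generally unstated; exclusion-with-report is this package's documented
  choice, and the pipeline aborts loudly if it happens on user data.

Later grafts may attach at an MRCA that includes earlier grafts, mirroring
iterative use of the congeneric-MRCA rule. Zero-length pendants (MRCA at the
tips) are permitted but flagged. The cophenetic matrix is computed by a
post-order sweep (depth(i) + depth(j) − 2·depth(MRCA)), O(n²), and is
cross-checked in tests against a graph-shortest-path oracle.

## Community structure

Richness is the Hill number of order 0 — the count of species present,
weighting common and rare species equally. Other Hill orders are out of
scope and raise.

MPD for a plot is the mean patristic distance over unordered pairs of
distinct present species; the abundance-weighted form is
Σ f_i f_j d_ij / Σ f_i f_j over i < j, which reduces to the unweighted form
on incidence data (the degenerate case in which "abundance-weighted" and
unweighted NRI coincide; the generator can emit Poisson abundances to
exercise the weighted branch non-trivially). Plots with fewer than two
species propagate NaN, never 0.

The independent-swap null preserves row and column occupancy sums exactly:
a step draws two plots and two species and, if the 2×2 occupancy pattern is
a checkerboard, swaps it diagonally (counts travel with the occupancy). The
chain is burned in for 10 × (occupied cells) attempted swaps and sampled
every 1,000 attempts by default; both knobs are configurable, and "number of
null communities" (default 1000) is deliberately separated from "swap
attempts per community", since "iterations" alone is ambiguous between the
two readings. On enumerable fibers (≤ 4×4 matrices) tests verify the chain
visits every matrix with the observed marginals at uniform frequency within
Monte-Carlo error; attempts are counted whether or not they produce a swap,
which is what makes the stationary distribution uniform.

NRI is the *negated* standardized effect size of MPD, so positive values
mean clustering. Null MPD uses the same weighting flag as the observed
value. sd(MPD_null) = 0 (e.g. a star phylogeny) yields NaN with a warning;
NaN plots are excluded listwise from SEM fits with a logged count.

## Piecewise SEM

The a priori DAG has temperature (MAT), precipitation (MAP) and forest-use
intensity (FUI, ordinal old-growth=1 < degraded=2 < secondary=3, treated as
numeric and scaled like any predictor) exogenous; PET endogenous on
temperature and precipitation; and the diversity response endogenous on
Temp, Precip, PET, PET² and FUI. PET² is a *derived covariate* of PET: it
enters regressions as a predictor but has no structural equation and
generates no d-separation claims — the standard treatment of quadratic
terms in regression-based SEM, and the one that keeps the basis set at one
claim (FUI ⫫ PET | Temp, Precip), df = 2. The PET² column is squared on the
raw scale before z-scoring.

All predictors (and Gaussian responses) are z-scored with the n−1
denominator; count responses are never scaled. Scaling a constant column is
an error, not NaN. With FUI balanced over 120 rows its scaled values are
±(x−2)/√(80/119) = ±1.2196 — note this uses the sample-sd convention
consistently rather than the population sd, which would give ±1.2247.

Component fits:

- **Gaussian** (NRI, PET): profiled REML for the single-random-intercept
  model, implemented here as a bounded one-dimensional search over the
  variance ratio with the fixed effects and residual variance profiled out
  analytically (Woodbury identity per group, pseudo-inverse GLS). A
  closed-form profile was chosen over a general mixed-model optimizer after
  the latter proved fragile exactly on this design: the quadratic PET term
  varies within a site only through plot-level jitter, so it is nearly
  collinear with PET within groups, which can make a multivariate search
  stall on the zero-variance boundary or fail outright. The profile agrees
  with statsmodels MixedLM to ~1e-4 on well-conditioned fixtures (enforced
  in tests) and cannot mis-converge, since the criterion is continuous in
  one bounded variable. One group degenerates to OLS with zero
  random-effect variance.
- **Poisson** (richness): Laplace-approximate maximum likelihood,
  implemented here (no installed Python package provides a frequentist
  Poisson GLMM). Each group's random-intercept integral is expanded around
  its conditional mode, found by a damped scalar Newton iteration (the
  integrand is log-concave, so this converges globally); the outer
  optimization over (β, log σ) uses L-BFGS-B, and standard errors come from
  the numerically differentiated Hessian. The fit matches lme4's `glmer`
  to ~1e-5 on a frozen oracle fixture (enforced in tests). If the mixed fit
  fails, the component falls back to a fixed-effects GLM with the site as a
  covariate and is flagged — with eight sites, robustness was preferred to
  silent failure. A near-zero random-effect variance is reported as a
  singular fit, warned about, and retained.

Wald (normal) p-values are used for edges and d-separation terms — one fit
per test, standard reporting. Each claim u ⫫ v | parents(u) ∪ parents(v) is
tested by refitting the downstream node's component model with the
claimed-independent variable added and taking that term's two-sided Wald p.
Fisher's C = −2 Σ ln p is chi-squared with 2k df; for df = 2,
P = exp(−C/2) analytically, which the implementation matches to 1e-6. A
p-value of exactly 0 is an error (infinite C), and a saturated DAG gives
C = 0, df = 0, P = 1.

Total effects decompose exactly: indirect(X → Y) = Σ over directed paths of
the product of standardized edge coefficients, total = direct + indirect
(verified against a path-enumeration oracle). PET² carries only its direct
edge — the quadratic term has no structural children, so no indirect paths
flow through it.

R² follows the mixed-model variance-partitioning scheme: marginal =
Var(Xβ̂) / (Var(Xβ̂) + σ²_site + σ²_resid), conditional adds σ²_site to the
numerator. For Poisson the observation-level variance on the latent (log)
scale uses the lognormal approximation ln(1 + 1/λ̄) with λ̄ the observed
mean count. Where a single published R² is compared against, the
conditional value is used, flagged as an interpretation in output metadata
(which of the two a given publication reports is often unstated).

## The synthetic generator

Defaults reproduce the target study design: 8 sites at (30, 650, 1000,
1500, 2100, 2500, 3100, 3500) m, 3 forest-use levels × 5 plots per site
(120 plots), a 689-species pool split over five life forms (tree 0.222,
shrub 0.179, herb 0.332, epiphyte 0.238, liana 0.029 — the field
proportions of such inventories). Climate functional forms are chosen for a
humid tropical mountain: MAT = 26 − 0.0055·elevation (°C; 5.5 °C/km lapse),
MAP = 800 + 1500·exp(−(e−1500)²/(2·800²)) mm (interior maximum ~2300 mm),
PET = 1400 − 0.9·e + 0.00025·e² mm (interior minimum at 1800 m). Plot-level
Gaussian jitter has sd = 1 % of each variable's across-site range. These
match the qualitative published patterns (linear decline, hump, U-shape)
without claiming the real surface values.

Assembly: plot richness is Poisson with log-mean = intercept + Σ β_k z_k +
u_site, u_site ~ N(0, 0.2²) on the log scale, intercept log(30); default
true β = (Temp 0.40, Precip 0.30, PET 0.23, PET² −0.12, FUI −0.12),
magnitudes echoing published total-richness effect tables. Members are
drawn without replacement with probability ∝
exp(−filter_strength·(optimum − MAT_plot)²/(2·niche_breadth²)) on a
Brownian thermal optimum (σ² = 4 °C²/unit branch length, root at the
gradient's mean MAT, niche breadth 5 °C, filter strength 1) — phylogenetic
niche conservatism, which clusters cold-site communities. Forest use enters
only through β_FUI on log richness, not through the filter, mirroring the
finding that disturbance does not structure phylogeny. Richness draws
exceeding the pool are capped with a logged warning. Genera are assigned by
an ancestor-closed partition of the birth–death tree (the n_genera − 1
shallowest internal nodes form the backbone; the hanging subtrees are the
genera), so genera are monophyletic by construction and grafting is well
defined.

What the generator does **not** emulate: real taxonomic composition, real
climate surfaces or their spatial autocorrelation, dispersal limitation,
species-abundance structure beyond optional i.i.d. Poisson counts, and
observation error in the inventories. Passing calibration tests therefore
shows the machinery is unbiased and recovers known signals under the
design's sampling structure — not that any particular field dataset meets
the models' assumptions.

## Problem sizes used in the test suite

Calibration tests run at sizes chosen to make their Monte-Carlo error small
relative to the asserted tolerances while keeping the suite quick: NRI null
calibration on the full 120-plot design with a 160-species pool and 1000
null communities; sign recovery of ±0.4 standardized effects over 50
replicate studies (200-species pools) at n = 120; d-separation type-I
calibration over 100 replicates; swap-chain uniformity on exhaustively
enumerated 3×4 and 4×4 fibers. The deposited-data reproduction runs at full
scale when the archived tables are supplied under `data/deposited/`.

## Known limitations

- Only one random-effect structure (a single random intercept) and the
  Poisson / Gaussian families are supported — matching the analyses in
  scope, not mixed models generally.
- With eight sites the climate covariates are strongly collinear (they are
  smooth functions of elevation), so individual coefficients in the
  five-predictor response model carry wide uncertainty even when the model
  as a whole fits; sign recovery and dominant-effect ordering are the
  reliable quantities, and the tests assert exactly those.
- d-separation claims involving a Poisson downstream node inherit the
  Laplace approximation's accuracy; with counts ≥ ~10 per plot (the regime
  here) the approximation error is far below the Wald test's own noise.
- The NRI sign convention (positive = clustering) is fixed; users of the
  opposite SES(MPD) convention should negate.
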