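# Methods

`sipaug` models and analyses bioaugmentation microcosm experiments in which
contaminated sediment is dosed with sulfamethoxazole (SMX) and optionally
inoculated with an exogenous degrader strain. The package has two halves: a
synthetic-experiment generator that produces the data products such a study
yields (concentration time series, ASV count tables, CsCl gradient fraction
profiles), and the inference stack that consumes them (kinetics, community
statistics, co-occurrence networks, stable-isotope-probing calls). This note
records the models, the defaults and why they hold, the numerical choices,
and the known limits.

## Experiment layout

The default design has five treatments — a sterilized control, an
antibiotic-free control (`non-SMX`), a non-inoculated SMX control
(`non-Inoc`), and two inoculated treatments (`Pseu.Inoc`, `Paen.Inoc`, at
inoculum OD600 = 0.01) — with 10 mg/L SMX added at days 0, 8 and 10. The
three inter-dose intervals are dosing phases I (days 0–8), II (8–10) and
III (10–11). Communities are destructively sampled at days 0, 1, 3, 5, 8,
10 and 11 with three replicates per treatment. All of these are
`ExperimentDesign` fields and validated invariants (contiguous phases,
doses only at phase starts, measurements inside the incubation window).

## Degradation model

Within a phase the true concentration follows first-order decay,

    C(t) = C_phase_start · exp(−(k_abiotic + k_bio)·Δt),

with the biotic term switched on only after a per-treatment lag (a hard
delay modelling slow induction of the catabolic genes), and each dose
resetting the concentration to residual + dose. Measurement noise is
multiplicative Gaussian (CV `noise_cv`, default 0.05), applied to the
observation only — it does not propagate into the state, so the latent
trajectory stays exactly exponential.

Default rates are calibrated once to the treatment narratives the design
emulates: `k_abiotic` = 0.004/day leaves the sterilized control at ~3.1 %
removal over 8 days (below the 3.5 % ceiling typical of sterile controls);
the non-inoculated phase-I `k_bio` = 0.0092/day yields 10 % removal in 8
days; the `Pseu.Inoc` system pairs a 1-day lag with `k_bio` = 0.23/day to
reach ~80 % by day 8 (≈70 percentage points above the non-inoculated
control — the kinetics report exposes both the absolute and the relative
reading of such comparisons); `Paen.Inoc` at 12/day clears the dose within
half a day. Phase-II/III rates are higher for the induced systems,
reproducing the re-addition acceleration.

`fit_first_order` regresses ln C on t within one phase (slope = −k), so
noiseless exponentials are recovered exactly. Values at or below the
quantification limit (0.05 mg/L by default) count as zero for efficiencies
and are excluded from log fits with a warning; a constant series is
reported as k = 0 with a `degenerate` flag rather than an error. Phase-II
and III fits start from the post-re-addition record: a dosing day carries
two records, the pre-dose residual filed under the phase it closes and the
post-dose concentration under the phase it opens.

## Community model

Latent abundances are log-normal baselines (`meanlog` 0, `sdlog` 1.5,
drawn once per experiment) times three per-sample factors:

* an independent log-normal jitter (sd 0.3),
* a **guild factor**: each ASV belongs to one of 8 guilds and scales with
  `exp(loading · coupling · z_guild)` where `z_guild` is a per-sample
  N(0, 0.8) draw, `coupling` ~ U(0.4, 1) and `loading` is −1 for 10 % of
  members. This plants the correlated co-abundance blocks (with a minority
  of negative associations) that the network stage thresholds at |ρ| > 0.6,
* **responder effects**: a responder's latent abundance is multiplied by
  `exp(effect · f)` where `f` is the fraction of all SMX added so far that
  has already been degraded in that microcosm — taxa that feed on
  degradation products rise with `f`, suppressed taxa fall.

An inoculated degrader occupies a fixed community share (default 20 %,
matching a heavy inoculum) that decays as `exp(−decay · t_depleted)` with
`t_depleted` the cumulative time SMX has been below the quantification
limit — an obligate degrader washing out once its substrate is gone.
Counts are multinomial at depth 10⁴ per sample. The closed-form latent
trajectory is exposed (`latent_abundances`) so tests compare sampled counts
against their exact expectation.

What the generator does **not** emulate: taxonomy and phylogenetic signal
in abundances (the UniFrac tree is an independent random coalescent),
temporal autocorrelation beyond the degradation coupling, overdispersion
beyond the log-normal–multinomial hierarchy, chimeras/contamination, and
library-size variation (all samples share one depth). Passing tests
therefore certify the inference machinery on a community with known
structure, not performance on any real sequencing run.

## Density-gradient model

Unlabelled buoyant density follows the Schildkraut relation
BD₀ = 1.660 + 0.098·GC (g/mL); full ¹³C labelling adds 0.036 g/mL, scaled
by each taxon's atom fraction excess (AFE). The gradient spans
1.690–1.755 g/mL in 12 fractions, indexed heavy-first (fraction 1 =
densest; loaders accept either order, but the convention is declared in
the file header and a mismatch between paired sets is an error, never a
silent fix). Each taxon's DNA mass spreads over fractions as a Gaussian
(sd 0.006 g/mL) integrated over the fraction bins, with the outer bins
extended to ±∞ so out-of-range densities accumulate at the edge fractions
(after a warning) and no mass is lost. Per-fraction 16S copies split the
qPCR total by DNA-mass share and sum to it exactly; per-fraction ASV
counts are multinomial at depth 10⁴. Fractions 3–10 are "sequenced" by
default. Per-fraction depth and qPCR totals are free parameters of the
design (10⁴ reads and 10⁸ copies by default, ordinary magnitudes for 16S
fraction libraries).

## Diversity and differential abundance

Alpha diversity uses the natural-log Shannon index, observed features, and
Pielou evenness H/ln(observed); a single-taxon sample has undefined
evenness and is reported as 0 with a flag. No rarefaction is applied by
default — every downstream statistic works on relative abundances or CLR
values; a rarefy-to-minimum helper would be easy to add but is not part of
the default path.

The CLR transform uses pseudocount 0.5 (also the Dirichlet prior), and
differential abundance follows the ALDEx2 recipe: per Monte-Carlo instance,
per-sample Dirichlet(counts + 0.5) draws → CLR → two-sided Wilcoxon
rank-sum per ASV; raw p-values are averaged over instances (16 by default)
and BH-corrected. `n_mc_instances = 0` is a deterministic single-pass mode
used for large null calibrations. Results are ranked by adjusted then raw
p with |median CLR difference| breaking ties, which keeps a strongly
enriched taxon ahead of a chance perfect-separator at the rank-sum floor.

Weighted UniFrac is Σ_b len(b)·|p_A(b) − p_B(b)| over branches, normalized
by Σ_b len(b)·(p_A(b) + p_B(b)) so distances lie in [0, 1] (the raw form is
a flag away). PCoA double-centers −D²/2; negative eigenvalues are reported
but contribute no axes, explained proportions are over the positive
spectrum, and each axis's sign is fixed by making its largest-magnitude
loading positive. PERMANOVA computes pseudo-F from among/within sums of
squared distances with the +1-corrected permutation p-value
(1 + #{F_perm ≥ F_obs})/(1 + n_perm), so p is never zero; a design with one
group returns R² = 0, and any group smaller than 2 raises.

## Networks

Per treatment, Pearson correlations between ASV relative-abundance
profiles across that treatment's samples (≥5 required) are thresholded at
|ρ| > 0.6 with the signed ρ stored on each edge: the absolute threshold is
used (with a positive-only flag) because ecological networks carry both
cooperative and exclusion links and the positive-edge share is itself a
reported property. ASVs below 50 % prevalence or with constant profiles
are excluded. No random-matrix-theory threshold selection is attempted —
the cutoff is fixed, transparent, and matches common practice.

Modules come from greedy modularity maximization (deterministic; module
ids ordered by size then lowest member id). Zi is the z-score of a node's
within-module degree against its module's members (Zi = 0 when the module's
degree spread is zero); Pi = 1 − Σ_t (k_it/k_i)². Roles follow the strict
threshold semantics: network hub (Zi > 2.5 and Pi > 0.62), module hub
(Zi > 2.5, Pi ≤ 0.62), connector (Zi ≤ 2.5, Pi > 0.62), else peripheral;
both boundaries belong to the peripheral side, and keystones are all
non-peripheral nodes, removed module-hubs-first (then network hubs, then
connectors; ties by descending degree, then id).

Natural connectivity is λ̄ = ln((1/N)·Σ e^{λ_i}) over the eigenvalues of
the unsigned, unweighted adjacency, computed with log-sum-exp; an empty or
edgeless graph is defined as 0. During removal experiments isolated nodes
are retained and N is the post-removal node count. Because λ̄ is a
per-node average, removing a sparse connector can *raise* it slightly —
only hub removal produces the sharp drops the robustness narrative is
about; the star-graph enumeration in the test suite makes this exact. The
equivalent-random-loss statistic reports the percent λ̄ drop from removing
the keystones and the smallest random-removal count whose mean curve
(`n_reps` uniform trajectories) drops at least as much; it always exists
because the curve reaches 0 when at most one node survives, and it is
undefined (an error) on a network whose intact λ̄ is already 0.

## SIP calling

Per gradient, each ASV's profile over the sequenced window is its relative
abundance within a fraction times that fraction's share of the window's
16S copies — a qPCR-weighted abundance whose matrix sums to 1, invariant
to rescaling the qPCR total. Heavy fractions are designated by density
(≥1.720 g/mL among sequenced fractions, the default) or as the k densest.
An ASV is called ¹³C-labelled iff all three hold:

1. enrichment ratio (heavy mean + ε)/(control heavy mean + ε) ≥ 2,
2. center-of-mass shift CM_labelled − CM_control ≥ 0.004 g/mL,
3. labelled heavy-fraction mean abundance ≥ 0.5 %,

with ε = 10⁻⁴. The rule is conjunctive because each part alone fails: the
ratio is pseudocount-sensitive for rare taxa, the CM shift alone flags
shifts too small to matter, and the abundance floor removes noise-level
profiles. All three sub-criteria are returned per taxon so users can relax
any of them — and relaxing a threshold can only add calls, never remove
one. These cutoffs are package defaults tuned to the generator's gradient
geometry, not values taken from any particular study's protocol.

Two intrinsic blind spots of heavy-fraction SIP carry over to the caller
and are reproduced, not hidden, by the generator: (i) a high-GC taxon
(GC ≳ 0.6, BD₀ ≳ 1.72) sits in the heavy fractions even unlabelled, so its
enrichment ratio stays near 1 regardless of labelling — the planted
degraders of the evaluation design therefore occupy the mid-GC band
(0.45–0.55), where unlabelled DNA is light and ≥50 % labelling moves it
into the heavy window; (ii) the abundance floor misses weakly labelled
taxa below ~1 % of the window mass, which is why the demo's 23-taxon
planting is only partially recovered while all of its strongly blooming
degraders are found with zero false positives.

## Seeds and problem sizes

One global seed expands into per-stage child seeds through NumPy
`SeedSequence` spawning; identical configuration + seed reproduces
bit-identical files (the manifest records SHA-256 digests). The test suite
and the acceptance script run the calibration studies at the sizes the
methods are specified for: 100-seed replicates for the SIP operating
characteristics, differential-abundance ranking and rate recovery, 500–1000
simulations at 999 permutations for the PERMANOVA type-I error, 50
randomized instances for the network-edge oracle, and the bundled demo
experiment (120 ASVs, 84 community samples) for the end-to-end run — sizes
chosen so the whole suite executes in well under a minute of CPU apiece
while keeping Monte-Carlo error far from the asserted bounds.

## Known limitations

* The generator's realism gaps listed above (no phylogenetic signal in
  abundances, no temporal autocorrelation, single depth).
* Quantitative SIP (per-taxon atom-fraction-excess estimation) is out of
  scope; the caller is a detector, not an estimator.
* Network inference ignores correlation significance (the design
  thresholds on ρ only) and compositional-correlation artefacts; the
  edge-set oracle guarantees fidelity to the stated rule, not robustness
  of Pearson-on-proportions itself.
* Kinetics fits assume first-order behaviour within a phase;
  Michaelis–Menten/Monod kinetics and metabolite accounting are out of
  scope.
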