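# Methods

This note documents the models, conventions and defaults behind
`spongetrace`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Tracer arithmetic

Bulk isotope values are handled as a strict conversion chain
δ ↔ R ↔ F with R = R_std·(1 + δ/10³) and F = R/(1+R).  Two conventions
are fixed deliberately:

- **Mole bookkeeping happens in atom-fraction space.**  Excess
  incorporation is (F_sample − F_baseline)·n_element; δ differences are
  reported separately as a descriptive quantity (`delta_change`) and are
  never multiplied by moles.  Near natural abundance the two framings
  differ negligibly (the linearisation excess ≈ Δδ/10³ · R_std/(1+R_std)²
  · n holds to 1% for |δ| < 50‰, property-tested), but at the
  1000‰-scale enrichments seen here the atom-fraction form is the correct
  one.
- **Negative excess is preserved.**  A sample below baseline is a real
  observation (net tracer loss, e.g. a host fraction respiring labelled
  carbon away) and is never clipped to zero.

Reference constants (overridable via the `ConstantsRegistry`): VPDB
¹³C/¹²C = 0.011180, atmospheric-N₂ ¹⁵N/¹⁴N = 0.0036765, atomic masses
C = 12.011, N = 14.007 g/mol.  These are community conventions, not
measurements; exposing them as configuration isolates the choice.

## Baselines and rates

Two baseline policies are implemented because the choice is genuinely
open in this design:

- `t0_mean` (default): mean atom fraction of the treatment-agnostic T₀
  samples per species × fraction.  It is the only option for sponges
  (which have no control treatment) and applies uniformly.
- `time_matched_control`: mean of the no-sponge control samples at the
  same chase timepoint (corals only).  Under drift-free controls the two
  coincide within measurement noise — asserted against the simulator.

Baseline averaging is done on atom fractions, not deltas; the baseline's
tabulated δ is the δ of the mean F.

The **rate denominator** ("mmol of element in the initial sample") is the
mean elemental pool of the T₀ samples of that species × fraction, not the
scored fragment's own pool: scored fragments are destroyed at sampling,
so the initial pool of the very fragment is unobservable, and the T₀
cohort mean is its natural estimate.  Rates exist only for chase
timepoints (T₃: 3 h, T₆: 6 h of exposure); a T₀ sample has no rate by
construction, and rate × exposure × baseline-mmol = excess holds exactly
(definition closure, tested).

Group summaries use linear-interpolation quartiles (the mainstream
boxplot convention; Tukey hinges were rejected to match it), whiskers at
the most extreme values within 1.5×IQR of the hinges, and points beyond
as outliers.

## Permutational statistics

PERMANOVA partitions the sums of squares of a distance matrix:
SS_total = n⁻¹Σ_{i<j}d²ᵢⱼ, SS_within = Σ_g n_g⁻¹Σ_{i<j∈g}d²ᵢⱼ, and
pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)).  Design choices:

- **Distances are Euclidean** for every pipeline response.  The responses
  are signed scalars (Δδ, excess, rate), for which ecological
  dissimilarities such as Bray–Curtis are undefined or misleading; on
  scalars the Euclidean pseudo-F is exactly the one-way ANOVA F, which is
  the central correctness oracle of the test suite.
- **Unique permutations.**  The p-value counts the observed arrangement
  into its own null set, p = (#{F* ≥ F} + 1)/(B + 1), so p ∈ [1/(B+1), 1].
  When the number of distinct label arrangements m is below min(10·B,
  10⁵) the null is enumerated exhaustively (p is then exact, count/m);
  otherwise B distinct arrangements are rejection-sampled without
  replacement.
- **Multi-factor calls** use sequential (Type-I) sums of squares through
  hat-matrix projections of the Gower-centred matrix G = −½CΔ²C, each
  term tested against the full-model residual, with free row permutation
  as the null.  Free permutation approximates residual permutation under
  a reduced model; for the balanced designs produced here the difference
  is small, and this is a documented limitation rather than a hidden one.
- **Pairwise follow-ups** are PERMANOVAs on each unordered group pair
  with Bonferroni adjustment p_adj = min(1, m·p); no other multiplicity
  correction is offered, matching how such post-hoc tests are usually
  reported in this literature.

The Kruskal–Wallis statistic is tie-corrected, and for N ≤ 10 an exact
permutation p accompanies the χ² approximation — at small n the two can
disagree substantially (for complete separation at n = (3,3), H = 3.857
carries χ² p ≈ 0.0495 but exact p = 0.1), so both are always reported
rather than silently trusting the asymptotic. Welch's t uses the
Welch–Satterthwaite df, hence the fractional degrees of freedom.

Calibration: under a three-group null the B = 999 permutation test
rejects at α = 0.05 at a rate inside [0.03, 0.07] over 2000 replicates
(acceptance-checked).

## Symbiodiniaceae density

cells/cm² = (count/volume)·dilution·homogenate-volume / surface-area — a
pure scaling chain, homogeneous of degree 1 in counts and −1 in area.
Any fixation dilution (e.g. a 1:1 paraformaldehyde step) belongs in
`dilution_factor` at load time, never hard-coded.  Surface areas are
consumed as numbers; the ImageJ-vs-foil comparison is a consensus report
(per-fragment ratios, Spearman ρ) and the pipeline uses the ImageJ
values, which are the more reproducible of the two methods.

## The simulator

### Model

Linear first-order kinetics were chosen as the minimal model that
reproduces the observed trajectory shapes (sponge enrichment rising
through the pulse, decaying through the chase; coral fractions rising
through the chase) while admitting closed-form solutions for oracle
tests.  Per element (C and N are independent; no covariance is modelled):

- *Pulse* (3 h): dSᵢ/dt = uᵢ·W_pulse with the reservoir held constant —
  the spike (≈10⁵ µmol ¹³C and ≈2.5·10⁴ µmol ¹⁵N in 84 L, from a
  0.1 g/L bicarbonate + 2 × 0.01 g/L nitrogen-salt recipe) exceeds total
  uptake by orders of magnitude.
- *Rinse* (1 h): unincorporated water label is discarded; sponge tracer
  holds.
- *Chase* (6 h, per enriched tank): dSᵢ/dt = −(rᵢ+ℓᵢ)Sᵢ,
  dW/dt = ΣrᵢSᵢ − Σc_jW, dX_j/dt = c_jW ± τ·(donor), dP/dt = ΣℓᵢSᵢ,
  where ℓ is an optional particulate leak into a pool P (default 0 — no
  visible detritus production is the emulated condition) and τ a
  host↔symbiont translocation rate.  **τ defaults to 0**: bulk time
  series cannot distinguish direct host uptake from translocation, so
  both pathways exist as separate parameters and the default attributes
  all host gain to direct uptake rather than asserting a mechanism.
  Mid-chase (T₃) fragments are removed destructively: their uptake stops
  and their tracer freezes, so the tank total (water + sponges + all
  fragments + particulate pool) is conserved exactly — the key invariant,
  held to ~10⁻¹⁵ relative.

Integration is fixed-step classical RK4 at dt = 0.01 h (enforced as an
upper bound), checked against the closed-form exponential solution of a
sponge-free tank to 10⁻⁹ relative.

### Default conditions

Defaults encode the experimental structure being emulated: 6 sponge
species (2 T₀ + 2 pulse-sampled individuals per species, 5 continuing
into one enriched tank each), 3 coral species × 2 fractions × 2 fragments
per species per tank, 5 enriched + 3 control tanks, 5 T₀ coral fragments
per species, measurement noise 0.1‰ on δ and 1% relative on %C/%N (the
stated analytical precisions), plus a lognormal per-individual multiplier
(CV 0.1) on uptake constants as mild biological variability.

Rate constants were set once from the enrichment magnitudes this type of
experiment reports, and are not tuning knobs:

- sponge pulse uptake uᵢ is derived in code from target pulse-end
  enrichments (Δδ¹³C from +28.6‰ for the strongest cyanobacteria-hosting
  species down to +0.5‰; Δδ¹⁵N from +400 to +1268.8‰), a 2 g dry
  individual at 35 %C / 5 %N, and the reservoir size;
- sponge release r spans 0.06–0.20 h⁻¹ for N (30–70% of the label
  released across the 6 h chase) and 0.05 h⁻¹ for C;
- coral uptake constants c (10⁻⁶–2·10⁻⁴ h⁻¹) produce per-sample excesses
  of ~10⁻³–4·10⁻² µmol ¹⁵N and 0–3·10⁻³ µmol ¹³C, with N ≫ C,
  symbiont ≫ host, the branching coral strongest, and the boulder-coral
  host at zero carbon uptake (its measured carbon flux is noise around
  zero and can be negative — deliberately);
- host/symbiont compositions (30/5.5 and 35/6.87 %C/%N) put the T₀ molar
  C:N means at ≈6.36 and ≈5.94.

Under these conditions the emergent per-species holobiont ¹⁵N:¹³C
fold-ratio lands between ~3.5 and ~11 — comfortably inside the 2.3–26.8×
envelope such experiments report.

### What the generator does *not* emulate

No inter-individual variation in background δ (baselines are exact at
zero noise — which is what makes the latent-truth oracle possible); no
species-level differences in elemental composition (so C:N species
contrasts are null in synthetic data); no control-tank drift; no
inorganic/organic partitioning of released label; no tank hydrodynamics
or pumping physiology.  Passing the synthetic tests therefore
demonstrates correctness of the arithmetic, bookkeeping, statistics and
kinetics — not that real reef data will satisfy model assumptions such as
first-order release or well-mixed tanks.

### Parameter recovery

Recovery of the coral uptake constants regresses pipeline-computed excess
on the known water-exposure integral ∫W dt of each fragment's tank
(through the origin — the model form when τ = 0).  At the default design
the smallest host-fraction ¹³C constants carry a single-experiment
standard error of ~6–8%: the host δ¹³C signal is only a few times the
0.1‰ measurement noise, and the T₀ baseline (n = 5) contributes a common
offset.  A max-over-constants 10% check on one experiment would therefore
fail a large share of seeds for any correct implementation, so recovery
is assessed on the mean recovered constant over 10 independent simulated
experiments, which isolates estimator bias from single-draw noise; the
observed worst-case error is 2–5% across master seeds.

## Degenerate inputs and tie-breaks

All-identical observations give a degenerate PERMANOVA (F = 0, p = 1,
flagged); all-tied values give Kruskal–Wallis H = 0 (flagged); two
zero-variance equal-mean samples give a degenerate Welch test (t = 0,
p = 1).  Permutation-F comparisons use a 10⁻¹² slack so that
machine-precision ties count as exceedances (conservative).  A zero or
negative ¹³C fold-ratio denominator is flagged `defined = False` rather
than dropped.  Row-level input violations (a sponge with an algal
fraction, a coral at the sponge-only pulse timepoint, out-of-domain
deltas) are rejected per row with reasons and line numbers, never
silently.

## Problem sizes

Default test and acceptance runs use the full default design (180 samples
per experiment), 2000 null replicates at B = 999 for calibration, 100
randomised configurations for conservation, and 10 experiments for
recovery — the whole suite completes in well under a minute of compute.
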