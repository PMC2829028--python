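# Model description and methods

## Scope

`aonsim` couples a discrete-time architectural model of a soybean seedling
(sowing to day 16, rhizobial inoculation on day 2) with a parcel-based
transport model of two mobile signals — root-derived Q and the
shoot-derived inhibitor SDI — to study autoregulation of nodulation (AON)
by computational complementation. It simulates intact plants of the
wild-type cultivar Bragg and its near-isogenic GmNARK loss-of-function
mutant *nts1116*, complemented mutants (*nts1116*+AON), and chimeric
grafts. It does not model carbon allocation, photosynthesis, 3-D geometry,
wound response at graft junctions, or the molecular identity of either
signal.

## Architectural model

Organs are 1-D segments on a rooted tree (hypocotyl base = root-system
base). Growth rules:

* Axes elongate linearly at a per-kind rate (mm/day), capped at a per-kind
  mature length. Organs attached at a parent's tip (cotyledons, the
  epicotyl, each next internode, petioles, leaves) ride the tip as it
  elongates, so branch nodes stay at the positions a real shoot keeps them.
* Shoot phytomers appear on a fixed 3-day plastochron: epicotyl + paired
  unifoliate leaves first, then internode + petiole + (trifoliate) leaf.
* Lateral roots initiate acropetally every `lateral_spacing` (6 mm) along
  the primary root, emerging once the tip has passed them by the
  susceptible-zone offset (laterals arise in the mature zone).
* Cotyledons senesce at day 9 and abscise at day 12 (inside the empirical
  7–14-day degradation window), with `biomass_fraction` falling linearly
  between the two; it scales their signalling capacity.
* Nodule primordia appear as a Poisson process in the susceptible zone
  `[tip − 35 mm, tip]` of every root that is still elongating and at least
  `susceptibility_age` = 2 days old (root hairs behind a brand-new tip are
  not yet infectable), at `primordium_density` = 0.12 primordia per mm per
  day after inoculation. Active primordia become nodules 4 days after
  initiation; arrested primordia never do.

The two genotypes share every growth parameter and differ only in
`nark_functional` flags; the loader enforces this near-isogenicity. The
architecture never reads signalling state, and signalling never draws
random numbers, so runs with the same seed are architecturally identical
across genotypes and signalling parameterisations — the property the whole
complementation comparison rests on.

Empirical organ-scale growth tables for these cultivars were not available;
the defaults in `data/defaults.yaml` are plausible stand-ins for a
glasshouse soybean seedling (primary root ≈ 229 mm by day 16, ~34 first-
order laterals, shoot of 5 phytomers) and are deliberately coarse on the
shoot, detailed on the root, because the root reports the phenotype.

## Signal transport

Signals are discrete mass parcels advected by plug flow along the organ
tree at a constant speed (mm/day): Q shootward (root → base → up the shoot),
SDI rootward. Flux converging toward the base never splits; flux diverging
toward distal tips splits at every branch junction:

* **Q (xylem-like):** in proportion to cross-sectional area (diameter²) of
  the receiving axes.
* **SDI (phloem-like):** in proportion to the *sink strength* downstream of
  each receiver, where a growing root tip's sink strength is its elongation
  rate × diameter². This routes the inhibitor to exactly the zones where
  new primordia form. Uniform and cross-section splitting are available as
  configuration options; both attenuate geometrically over the ~30 root
  junctions and starve the advancing susceptible zones, which is why they
  cannot produce a regulated wild type in this architecture.

Parcels reaching a terminal tip rest there (tips are sinks); parcels in an
organ are merged on a 5-mm grid once per growth step — merging conserves
mass and first moment, and doing it once per growth step (not per sub-step)
keeps the resulting numerical diffusion independent of the signalling
sub-step. Transport conserves mass exactly; only first-order decay
(default 0 for both signals — no empirical decay information exists),
perception, and organ abscission remove signal.

## Perception, production, inhibition

Each primordium emits a single pulse of 1 unit of Q at initiation, placed
at its attachment point (pulse emission, not sustained: the induction event
is the signal source). In NARK-functional aerial organs (leaves,
unifoliate leaves, and — under the cotyledon-shoot hypothesis only —
non-abscised cotyledons scaled by biomass fraction and graft retention
capacity), Q converts to SDI with first-order kinetics at `sdi_gain` =
2/day; perception consumes the converted Q (mass accounting stays closed;
a catalytic mode is a config switch). Complementation runs impose the
hypothetical receptor on every aerial organ regardless of genotype
(`override_nark`), which is what "adding AON" to the mutant means; graft
runs instead follow each organ's own genotype flags.

A nodule primordium younger than `commitment_age` = 1.5 days is arrested
when the local SDI concentration — parcel mass in a 10-mm window of the
parent root, per mm — reaches `t_inh`. Older primordia are committed and
immune, which is how the earliest (crown) nodules survive in the wild
type: the first SDI reaches the root ≈ day 4.2 at the reference transport
rates, just after the day-2 cohort has committed. With a 2-day commitment
age that cohort is still vulnerable when SDI arrives and the crown is lost,
which is why 1.5 days is the default.

## Multi-rate synchronisation

Each growth step (0.25 day) is followed by ⌈growth_dt/dt_signal⌉ signalling
sub-steps (default dt_signal = 0.025 day) in fixed order: emit (first
sub-step) → advect Q → perceive/produce → advect SDI. Arrest is decided
once per growth step on the **time-averaged** local SDI concentration
accumulated over the sub-steps. Averaging, rather than sampling
instantaneous concentrations, makes the arrest decision a Riemann integral
that converges under sub-step refinement; instantaneous thresholding is
dominated by transient spikes of passing parcels and does not converge.
At the default resolution, halving dt_signal changes the day-16 wild-type
nodule count by <5%.

## Baselines, the grid, and S_cp

The similarity degree compares three runs sharing one seed and schedule:
the mutant architectural model (no signalling), the wild-type reference,
and the complemented mutant. Because no empirical wild-type data exist
here, the wild-type reference is the Bragg genotype run *with* the
reference AON parameterisation (the mid level of each grid factor). Two
consequences follow by construction: the near-isogenic invariant makes the
mid-level cotyledon-shoot cell the very same simulation as the reference,
so its S_cp is exactly 100%; and S_cp at the degenerate limit (all-zero
AON) is exactly 0%.

Grid levels: transport rates {25, 50, 100} mm/day for both signals;
inhibition thresholds {0.003, 0.006, 0.012} units/mm, the mid level chosen
so the reference wild type is well regulated (≈5-fold fewer nodules than
the mutant, crown-clustered). Labels CRH_i/CSH_i are assigned in
lexicographic order of the (r_q, r_sdi, t_inh) level indices; CRH_i and
CSH_i share levels and seed, differing only in the cotyledon's role.

"Nodulation interval" is operationalised as the interquartile range of
nodule depths (path distance from the root-system base); the goodness
criterion is inclusive at both bounds (80% and 120% are *good*).

Replication: one seeded run per grid cell by default (integer nodule
counts, no averaging); graft comparisons use means over 5 seeds.

## Grafting

A chimera is assembled from shoot / cotyledon / root parts, each carrying
its genotype's NARK flags (growth parameters are identical anyway); the
graft junction is transport-transparent. Cotyledon retention states are
imposed schedules at the graft day (default day 4): `0_C` abscises both
cotyledons, `1_YC` abscises one and leaves the survivor at 40% capacity,
`2_YC` keeps both at 40%, `2_GC` keeps both at full capacity. The retained
capacity of a yellowing cotyledon is not quantified empirically; these are
declared stand-ins.

## What the defaults do and do not reproduce

Reproduced on the shipped defaults (seed 1, or means over seeds 1–5):
supernodulation (261 vs 50 nodules at day 16); crown-restricted wild-type
nodulation (mean depth 34 vs 57 mm, IQR 22 vs 38 mm); cotyledon-shoot
complementations scoring far above cotyledon-root ones (mean day-10 S_cp
78% vs 48%); mutant-shoot grafts out-nodulating wild-type-cotyledon grafts
(Ns+Nc+Br 257 vs Ns+Bc+Br 147); and regulation weakening monotonically as
cotyledons are yellowed or lost (0_C 240 ≥ 1_YC 184 ≥ 2_YC 182 ≥ 2_GC 147).

Not reproduced: the late reversal in which the graft starting *without*
wild-type cotyledons (Bs+Nc+Nr) ends up with *fewer* nodules than its
counterpart (Bs+Bc+Nr) — under these defaults the extra early Q does not
translate into enough extra SDI to overtake; the corresponding test is a
characterisation, not an assertion. Exact per-cell similarity-degree
values of the original heat maps depend on unavailable empirical growth
tables and experiment conditions and are out of scope; only the qualitative
directions above are claimed, and only for the synthetic parameter sets —
passing tests show internal consistency of the model, not fidelity to any
particular glasshouse dataset.

## Numerical and degenerate-input notes

* Growth step 0.25 day; day-16 horizon; snapshots at days 10 and 16.
* Transport is exact (event-driven parcel advance); conservation holds to
  1e-9 relative in the tests.
* `t_inh = 0` or `∞` disables arrest cleanly; `sdi_gain = 0` or
  `q_per_primordium = 0` reduces any run to the architectural model,
  bit-for-bit.
* S_cp is undefined when the mutant baseline does not out-nodulate the
  wild-type reference; `run_grid` aborts with a diagnostic rather than
  returning quiet nonsense.
* All randomness flows through one `numpy` Generator seeded from the run
  seed; identical (parameters, seed, schedule) runs are bit-identical,
  including CSV exports.
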