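# aonsim default study conditions (schema aonsim-defaults/1).
#
# All tunable defaults of the simulator live here: organ-scale growth
# parameters shared by the near-isogenic genotypes, the NARK-functionality
# flags that distinguish wild-type Bragg from the supernodulating mutant
# nts1116, the reference AON signalling parameter set, the 3x3x3
# virtual-experiment grid levels, graft retention capacities, and the
# simulation schedule.  Nothing in the code hard-codes these numbers.
#
# Units: lengths mm, rates mm/day, times days, signal in arbitrary units
# (one unit = the Q pulse of one primordium), concentrations units/mm.
schema: aonsim-defaults/1

growth:
  # Initial organ lengths at birth (mm).
  initial_length:
    hypocotyl: 35.0
    epicotyl: 2.0
    internode: 2.0
    petiole: 4.0
    leaf: 4.0
    unifoliate_leaf: 4.0
    cotyledon: 10.0
    primary_root: 5.0
    lateral_root: 1.0
    nodule_primordium: 0.5
    nodule: 3.0
  # Elongation rates (mm/day).  The hypocotyl is treated as fully extended
  # at day 0 (soil emergence); cotyledons do not elongate.
  elongation_rate:
    hypocotyl: 0.0
    epicotyl: 8.0
    internode: 10.0
    petiole: 7.0
    leaf: 10.0
    unifoliate_leaf: 8.0
    cotyledon: 0.0
    primary_root: 14.0
    lateral_root: 6.0
    nodule_primordium: 0.0
    nodule: 0.0
  # Mature lengths (mm); the primary root reaches ~229 mm by day 16.
  max_length:
    hypocotyl: 35.0
    epicotyl: 30.0
    internode: 45.0
    petiole: 30.0
    leaf: 60.0
    unifoliate_leaf: 45.0
    cotyledon: 10.0
    primary_root: 240.0
    lateral_root: 80.0
    nodule_primordium: 0.5
    nodule: 3.0
  # Axis diameters (mm), used for cross-section weighted flux splitting.
  diameter:
    hypocotyl: 2.5
    epicotyl: 2.0
    internode: 1.8
    petiole: 1.0
    leaf: 1.5
    unifoliate_leaf: 1.2
    cotyledon: 1.6
    primary_root: 1.2
    lateral_root: 0.4
    nodule_primordium: 0.5
    nodule: 2.0
  phytomer_interval: 3.0          # days between successive shoot phytomers
  lateral_spacing: 6.0            # mm between lateral-root initiations
  susceptible_offset: 35.0        # mm of root behind the tip open to infection
  susceptibility_age: 2.0         # days before a young root becomes infectable
  primordium_density: 0.12        # primordia per mm susceptible zone per day
  primordium_maturation_age: 4.0  # days from initiation to emerged nodule
  cotyledon_senescence_day: 9.0   # cotyledons yellow (within the 7-14 d window)
  cotyledon_abscission_day: 12.0  # cotyledons shed

genotypes:
  bragg:
    # GmNARK is transcribed everywhere but functions as a nodulation-control
    # receptor only in aerial photosynthetic organs; whether the cotyledon
    # flag is *used* is decided by the cotyledon hypothesis of the run.
    nark_functional:
      leaf: true
      unifoliate_leaf: true
      cotyledon: true
  nts1116:
    # Loss-of-function GmNARK: no organ can trigger SDI production.
    nark_functional: {}

signalling:
  # Reference AON parameter set (the "confirmed mechanisms" baseline).
  r_q: 50.0              # mm/day, shootward Q transport
  r_sdi: 50.0            # mm/day, rootward SDI transport
  q_per_primordium: 1.0  # units of Q emitted per primordium initiation
  sdi_gain: 2.0          # per day, Q -> SDI conversion rate in NARK organs
  t_inh: 0.006           # units/mm, local SDI concentration arresting primordia
  decay_q: 0.0           # per day
  decay_sdi: 0.0         # per day
  commitment_age: 1.5    # days after which a primordium cannot be arrested
  dt_signal: 0.025       # days, signalling sub-step
  bin_mm: 5.0            # mm, parcel merge resolution
  conc_window_mm: 10.0   # mm, window for local SDI concentration
  split_rule: cross_section  # Q flux split at junctions (xylem-like):
                             #   cross_section | equal | sink
  split_rule_sdi: sink       # SDI flux split (phloem-like, toward growing
                             # root tips): cross_section | equal | sink
  catalytic: false       # if true, perception does not consume Q
  override_nark: false   # complementation runs force shoot-organ perception

grid:
  # Virtual-experiment factor levels (low, mid, high).  The mid level of
  # each factor is the reference signalling value above, so the mid-level
  # cotyledon-shoot cell reproduces the wild-type reference exactly.
  r_q: [25.0, 50.0, 100.0]
  r_sdi: [25.0, 50.0, 100.0]
  t_inh: [0.003, 0.006, 0.012]

grafting:
  graft_day: 4.0
  # Fraction of full cotyledon SDI capacity retained per cotyledon after
  # the graft day; 0_C and 1_YC additionally remove two / one cotyledons.
  retention_capacity:
    "0_C": 0.0
    "1_YC": 0.4
    "2_YC": 0.4
    "2_GC": 1.0

schedule:
  end_day: 16.0
  growth_dt: 0.25
  inoculation_day: 2.0
  snapshot_days: [10.0, 16.0]
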