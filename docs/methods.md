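# Methods

This note documents the models and procedures implemented in `mbx`, the
parameters that matter, the synthetic data the package is validated on,
and the numerical choices made where the underlying study leaves the
design open.

## Skeleton model and morphometry

A neuron skeleton is a single rooted tree of 3-D nodes in nanometres (the
convention of whole-brain EM volumes); edges are straight Euclidean
segments between consecutive nodes, with no spline smoothing. SWC (7
columns, `#` comments, parent −1 for the root) is the interchange format;
a configurable unit scale brings micrometre files to nm. Parsing enforces
the tree invariants (unique ids, one root, resolvable parents, no cycles)
and names the offending line on failure.

*Strahler order* follows the textbook stream-order definition: leaves are
1; an internal node takes its children's maximum, +1 when at least two
children tie at that maximum. *Geodesic distance* between two nodes is the
cable length along the unique tree path, computed through the lowest
common ancestor in O(depth); both algorithms are cross-checked against
independent oracles (naive recursion; Dijkstra on the weighted graph) on
1,000 random trees.

*Dendritic root.* Anatomically this is the point where the main neurite
splits into proximal dendrites and distal axon; the source study located
it by inspection, not by an algorithm. When a `dendritic_root` tag is
present it wins. Otherwise we infer it with a synapse-flow separation
score: for every branch point and each of its child subtrees, score =
(postsynapses inside + presynapses outside) / total sites, maximized also
over the mirrored assignment (presynapses inside), since either side of
the split may be the axon. The arg-max branch point is returned; ties
break to the smallest node id for determinism. On generated skeletons with
clean axon/dendrite separation this recovers the planted split in ≥ 99%
of 200 seeded instances (in practice 100%).

*Axonlets* are presynapse-only neurites arising within the dendritic
field. We return maximal subtrees hanging off field nodes (nodes strictly
below the dendritic root whose subtree still contains a postsynapse) that
carry ≥ 1 synaptic site, all presynaptic. Two consequences worth knowing:
a maximal axonlet may include synapse-free twigs above the planted
neurite, and two axonlets attached to the same synapse-free branch merge
into one — both follow from maximality and are treated as correct by the
tests (presynapse counts, not subtree identity, are compared).

## Synapse-placement statistics

Distance profiles measure each site of a class at its node on the focal
neuron (postsynaptic node for inputs, presynaptic for outputs), geodesic
to the dendritic root, in absolute nm (a relative-to-extent mode was
considered and rejected as the field's default; absolute distances are
what the planted distributions control).

Profiles are fit with 1- and 2-component Gaussian mixtures (EM via
scikit-learn) and selected by BIC. Initialization is deterministic —
sample mean for k=1, the 25th/75th percentiles with equal weights and the
sample variance for k=2 — so a fixed seed fixes the fit. Fits require
n ≥ 10 and non-zero variance. On 200 seeded planted skeletons (n = 500
distances; bimodal components ≥ 5 sd apart) the selector must be ≥ 95%
correct; the shipped conditions give 100%.

Localization of two classes is compared by a two-sided Mann-Whitney
rank-sum test plus the signed median difference (a − b; positive = a more
distal). The degenerate 1-vs-1 case reports p = 1 by convention.

*Synapse-count bounds.* The tracing protocol's published detection rates
are: 99.8% of presynapses and 91.7% of postsynapses found; 2.2% of
annotated postsynapses are false positives (presynaptic false positives
negligible). The bound formula corrects an annotated count `found` as

    lower = found · (1 − 0.022)
    upper = found · (1 + (1 − 0.917) · (1 − 0.022))

with half-away-from-zero rounding to one decimal. The study prints the
resulting bounds but not the formula; this parameterization reproduces
every printed cell — (16.6, 18.4), (15.6, 17.3), (46.0, 50.8) from found
counts 17, 16, 47 — which is the package's acceptance check for it.

*Dendrograms* encode topological (not metric) depth from the root on the
y-axis, with leaves at consecutive x in file order and internal nodes at
the mean of their children; the laid-out edge set is exactly the
skeleton's edge set, and synapse marks pass through with their node ids.

## Imaging quantification

Two baseline conventions: `pre_odor_2s` (F₀ = mean F from 2 s before odor
onset up to onset; used for conditioning experiments, one baseline per
stimulus) and `first_9s` (F₀ = mean of the first 9 s; used for
optogenetic connectivity experiments). ΔF/F₀ = (F − F₀)/F₀; a
non-positive F₀ is an error. Onsets snap to the nearest sample of the
native 5.92-Hz grid.

The odor response is the trapezoidal integral over the 5-s odor window.
The default integrand is F/F₀ (ΔF/F₀ + 1), matching the stated
convention; ΔF/F₀ integration is available (`integrand="dff"`), and
matters when interpreting ratios: dividing by the novel-odor AUC cancels
a planted multiplicative effect exactly only for the baseline-subtracted
integrand (a 30% depression gives a CS+/CS− ratio of 0.70 under `dff`,
but a smaller shift under F/F₀ because of the constant ×5 s window term).
Per-fly normalization divides each AUC by the same fly and trial's
novel-odor (IAA) AUC; near-zero novel AUCs (|AUC| < ε, default 10⁻⁹)
are flagged and excluded with a warning.

Cohort comparison: Shapiro-Wilk on the paired CS+ − CS− differences at
α = 0.05 gates a paired t test (normal) vs a Wilcoxon matched-pairs
signed-rank test (otherwise) — the study names the two tests but not the
gate; Shapiro-Wilk at 0.05 is the standard deterministic choice.
All-zero differences are reported as a degenerate case with p = 1.
Optogenetic responses compare mean ΔF/F₀ over [onset − 1 s, onset)
against [onset, onset + 1 s) with a paired t test.

## Behaviour and protocols

PI = (N_CS+ − N_CS−)/N_total; non-choosing flies are counted in the
denominator by default (the "total number of flies" reading) and can be
excluded. A biological sample is the mean of two reciprocally trained
groups. Group comparisons use an unpaired t test for two groups and
one-way ANOVA + Tukey HSD beyond that, two-sided at α = 0.05; a
`posthoc=False` switch skips the Tukey table in simulation sweeps.

The protocol compiler turns a declarative spec into a timed event list.
Standard training: 1-min CS+ with twelve 90-V shocks at 5-s intervals,
first shock 1.2 s after odor onset (stated for under-the-microscope
training; applied generally and configurable), then 45 s of clean air and
1-min CS− unshocked. A shock train that would outlast the CS+ window is
rejected. Re-exposures are unreinforced 1-min odor presentations; the ITI
is measured from the end of one trial to the start of the next, so a
15-min ITI spaces consecutive onsets by 16 min. Temperature shifts are
annotations only (no kinetics). Timelines are deterministic and
round-trip through JSON.

## Circuit model

A rate-based, discrete-trial model (no spiking, no time constants; one
plasticity update per trial) of four compartments: γ1pedc (MVP2,
approach), γ5 (M6, avoidance), β′2 (M4β′, avoidance), and a lumped
"approach-other" channel. KC→MBON weights start at 1 (balanced network:
naive valence is odor-independent for equally sparse odors, which the
generator guarantees by using disjoint odor patterns of equal active
count).

Forward pass for odor **k** (binary KC vector):

    mvp2      = w_γ1pedc · k                (no inhibition upstream)
    m6_axon   = (w_γ5 · k) / (1 + g_shunt · mvp2)     divisive
    m4_axon   = max(0, w_β′2 · k − s_sub · mvp2)      subtractive
    dan_γ5    = dan_gain · (m6_axon + m4_axon)
    valence   = (mvp2 + approach_other) − (m6_axon + m4_axon)

The divisive/subtractive split is an interpretive encoding of the
EM placement result (root-clustered MVP2 synapses can shunt the whole M6
dendritic tree; distal boutons on M4β′ act locally) and is flagged as
such.

Plasticity is dopamine-gated multiplicative depression restricted to the
listed compartments and to exactly the odor-active KCs:
`w ← max(w_min, w·(1 − η))`. Training (CS+ with PPL1) targets γ1pedc and
approach-other; extinction targets only γ5, per the observation that the
M4β′ response is unchanged by extinction. During re-exposure the γ5 DAN
drive is computed from the *current* CS+ axonal response and triggers
depression only above `dan_threshold`; blocking M4/M6 output zeroes that
recurrent drive, and blocking the γ5 DANs vetoes the update.

All quantitative parameters are this package's choices — the biology
constrains only signs and wiring. Defaults (one config block in
`CircuitState`):

| parameter | default | why |
| --- | --- | --- |
| N KCs / active fraction | 200 / 0.10 | sparse odor code at desk scale |
| g_shunt | 0.05 | naive shunt halves M6 output (20 → 10) |
| s_sub | 0.4 | naive subtraction leaves M4 positive (20 → 12) |
| η_train | 0.5 | one trial halves CS+ drive to MVP2 |
| η_extinction | 0.134 | solves (1−η)² = (1 + g·mvp2⁺)/(1 + g·mvp2⁻): two re-exposures equalize m6_axon(CS+) and m6_axon(CS−), the measured endpoint of extinction |
| dan_threshold | 25 | between naive (22) and trained (29.3) recurrent drive, so only the trained network triggers extinction |
| w_min | 0.05 | depression floor |
| ε (PI softening) | 40 | ≈ 2× naive compartment drive; without it the PI ratio saturates at ±1 whenever the two valences differ in sign |

With these defaults the model reproduces the full qualitative table:
post-training MVP2 depression with unchanged M6 dendrite but potentiated
M6/M4 axonal CS+ responses (disinhibition); post-extinction persistence
of MVP2 depression, new M6 dendritic depression, near-equal M6 axonal
responses, unchanged M4; PI ≈ −0.41 trained, −0.37 after two
re-exposures, pinned at −0.41 under γ5-DAN or M4/M6-output block, −0.49
after retraining; and full invariance of never-trained odors.

## Synthetic data

The generators define the study conditions the tests run under.

*Skeletons*: a short trunk (soma → planted dendritic root), then a
dendritic arbor (60% of remaining nodes) and an axonal arbor grown by tip
extension with branching probability 0.25 and Gaussian segment lengths
(1.5 ± 0.3 µm). Synapse classes are planted by sampling a target geodesic
distance from the requested distribution (uniform / Gaussian / bimodal)
and snapping to the nearest candidate node of the class's domain; targets
outside the arbor are resampled with a warning (error after 100
attempts). Axonlets grow as single subtrees off interior dendritic nodes.
Not modelled: tortuosity, taper, spine-like twigs, contralateral arbors.

*Imaging cohorts*: one trace per fly at 5.92 Hz with the test sequence
CS+, CS−, novel (5 s each, 30 s air between, grid-aligned onsets).
Responses rise exponentially (τ 0.3 s) to a plateau during the odor and
decay (τ 1.5 s, truncated at 10τ so trials are exactly independent);
amplitude = baseline (100 a.u.) × 0.6 × per-fly lognormal gain (cv 0.25)
× per-odor lognormal jitter (cv 0.10), with the CS+ scaled by the planted
multiplier (0.7 / 1.3 for ±30% effects); additive Gaussian noise on F
(sd 2). Photobleaching, motion and GCaMP nonlinearity are not modelled,
so passing tests demonstrate pipeline correctness on clean-but-noisy
data, not robustness to those artefacts.

*T-maze*: each fly independently chooses the CS+ arm with probability
(1 + PI_true)/2 — pure binomial choice, no group-size or odor-bias
effects.

Determinism: identical spec + seed gives byte-identical output; one
global seed fans out to independent substreams (`SeedSequence.spawn`).

## Problem sizes and tolerances

The standard evaluation runs (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 1,000 random trees (≤ 200 nodes) for the
oracle checks; 200 planted skeletons (500-node trees, 500 distances) for
mixture selection and 50 for localization ordering; 100 seeded cohorts of
15 flies per planted imaging effect plus 1,000 null cohorts for the
type-I rate (accepted within [0.035, 0.065]); 1,000 groups of 100 flies
for the T-maze estimator (mean PI within 2 binomial SEs of −0.4). These
sizes make the whole evaluation complete in about a minute on one CPU
while keeping Monte-Carlo error well below every margin tested.

## Known limitations

- The dendritic-root score assumes pre/post segregation; neurons with
  heavily mixed arbors (or axonlet-rich fields) can pull the arg-max away
  from the anatomical split.
- The bound formula is a reconstruction that exactly matches the printed
  table; alternative rate parameterizations that fit less well cannot be
  excluded from first principles.
- The circuit model is a sign-structure model: magnitudes (including the
  per-trial extinction step and spacing effects between ITIs) are not
  mechanistically derived, and trial-count monotonicity is the only
  claim made about repeated re-exposure.
- Whether extinction-relevant γ5 DANs coincide with the reward-coding
  subset is left open in the source study; the simulator treats them as
  one population.
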