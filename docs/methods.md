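# Methods

## Scope and model

`socioscan` treats social-network inference from Bluetooth (BT)
proximity logs as *edge inference with validation*: the nodes (a class
roster) are known, the task is to decide which pairs are genuinely
connected, and every candidate decision rule is scored against an
independent ground-truth (GT) network rather than hand-tuned. The
pipeline has four stages — data-quality filtering, weighted network
construction, brute-force parameter validation, and structural
comparison — plus a synthetic-study generator that stands in for field
data.

## Data-quality filters

Two filters precede any analysis. A class is admitted when its survey
participation rate is *strictly* greater than a threshold (default
0.60): nomination data degrade quickly below that, since a 40%-sampled
class reveals only 40% of every member's relations. Within a log, scan
periods with fewer than `min_obs` records (default 30) are dropped as
trivial; counts are aggregated per (wave, period) over days by default,
with a per-(day, period) variant available since field deployments
differ in whether a slot that worked on one day worked on another.
Detections of devices not on the roster are excluded, not added:
the analysis is a within-class network.

## Connection weight

For a pair (i, j),

w(i,j) = (num_connections(i,j) + num_connections(j,i) + α) /
(num_scans(i) + num_scans(j) + β),

where `num_connections(i,j)` counts distinct (wave, day, period) slots
with an i→j detection and `num_scans(i)` counts distinct slots in which
i logged at least one detection. A "successful scan period" is
observable only through logged detections — an empty successful scan is
indistinguishable from a failed one in the detection-only schema — so
the scanner-side definition is used; slots in which i was merely
detected by others do not count. Defaults α = 0, β = 1 bias weights
toward 0 and penalize pairs with low combined scan activity; with
β ≥ 1 every weight lies in [0, 1). Both constants are exposed. With
α = β = 0 a pair whose summed detections equal summed scans has weight
exactly 1 regardless of activity level, which is the imbalance the
smoothing exists to break; the weight denominator being zero in that
configuration raises an error rather than returning NaN.

Thresholding is strict (edge iff w > threshold). Directed networks
carry two equal opposite arcs per qualifying pair — the direction
parameter probes the *design decision*, not asymmetric weights.
Isolated roster nodes are always retained: their prevalence as the
threshold rises is itself a diagnostic (it motivates capping the
threshold grid at 0.6).

## Ground truth

Directed GT weight i→j = (#distinct items on which i nominated j)/6;
undirected = pooled both-direction count / 12. Repeat nominations of
the same peer on the same item count once (items are binary single-item
measures). An edge exists at any positive weight — an undirected edge
does not require mutual nomination; the pooled formula implies any
positive sum suffices, and a strictness switch would change GT
semantics, so none is defaulted. Binary friendship matrices are read
as unit-weight networks, undirected when symmetric.

## Validation search

The grid is the Cartesian product of: thresholds {0.01, 0.02, …, 0.60}
(60 values; 0.0 is reserved for the baseline scenario), cumulative
day-window prefixes (D1; D1–D2; …), cumulative scan-period prefixes
over the *eligible* (post-filter) periods, and connection type. With 5
days and 16 eligible periods this is 4800 candidates per connection
type. Windows are prefixes, not arbitrary subsets: the question the
window parameter answers is "how many days/slots of collection
suffice", which only prefixes address. One published account of this
design lists 15 scan-period labels while stating that 16 were used and
that the grid had 4800 points; the arithmetic (60 × 5 × 16) is taken
as authoritative.

Scoring is edge-wise classification over the full roster pair universe
— N(N−1) ordered pairs directed, N(N−1)/2 unordered pairs undirected,
isolates and scan-silent roster members included, since accuracy is
defined over the class network. Accuracy suits the near-balanced edge
classes of close-knit classrooms; MCC is provided for sparse networks
(large cohorts) where accuracy saturates. MCC's zero-denominator case
(any empty confusion margin) returns 0, the standard convention.
Within a window, pair weights are computed once and re-thresholded per
grid value; this is exactly equivalent to rebuilding each network and
is what makes the full grid run in seconds.

Distinct-network accounting hashes canonical sorted edge sets; distinct
metric values are counted after rounding to 4 decimals (configurable),
matching the precision at which such accuracies are conventionally
reported. Optimal selection is argmax metric → min BT observations
used → min days → min scan periods → lexicographically smallest
parameter tuple. The final lexicographic step is ours: the preceding
rules can still tie, and selection must be deterministic.

## Structural metrics

All on binarized graphs. Density includes isolates in N. Gender
assortativity is Newman's discrete coefficient on the edge-end mixing
matrix, computed via networkx; a graph whose connected nodes all share
one gender yields NaN (undefined), never 1. Freeman centralization
C = Σ(c_max − c_v)/H with star-calibrated normalizers: H = (n−1)(n−2)
for undirected degree, (n−1)² for in-degree on directed graphs (for
undirected networks plain degree is the "in-degree" column), and
(n−1)(n−2)/(2n−3) for closeness on the Wasserman–Faust scaled
closeness, which remains defined on disconnected graphs (BT networks
can contain isolates). Node centralities are raw tie counts (degree,
in-degree) and power-iteration eigenvector centrality (tol 1e−9, max
10000 iterations) rescaled to max 1. GT/BT comparison reports
side-by-side values, deltas, and the Spearman correlation of the two
degree vectors (constant vectors: 1 if identical, else NaN).

## Synthetic studies

The generator emulates one school class over one wave. Defaults: 15
pupils, 53% girls, homophily 0.7 (probability a nomination attempt
targets a same-gender peer), 3 hub pupils with 3× nomination weight, a
mean of 7 nominees per pupil, items per tie min(6, 1+Poisson(1.5)),
five days of quarter-hour slots over 07:00–19:00 (48 slots, half-open
tiling), and per-slot scanner participation 0.18 — field deployments
of this kind report participants collecting data in roughly a fifth of
scheduled slots. Detection: a scanning pupil detects a co-participating
tied peer with p_detect_edge·(1−p_miss) (defaults 0.6, 0.1) and a
co-participating untied peer with p_false_positive (default 0.02),
pairwise-independently per slot — the simplest model of coincidental
proximity; correlated co-location is out of scope. The
`mean_out_degree` control exists because planted GT density must match
classroom reality (≈0.5 directed) for the validation problem to be
near-balanced. Randomness uses per-(day, slot) substreams derived from
the single config seed, so output files are bit-identical across runs.

What the generator does *not* emulate: spatial/mobility structure,
RSSI, battery decay, school-timetable periodicity in participation, or
correlated false positives (a crowded hallway lighting up many pairs at
once). Tests passing on synthetic logs therefore demonstrate
correctness of the machinery and its behavior under independent noise,
not field performance.

## Calibration experiments and problem sizes

The test suite runs the pipeline at desk scale, chosen so the full
suite completes in well under a minute of compute per experiment: the
noiseless-identity check uses 12 nodes, 3 days × 8 slots; the
threshold-vs-baseline experiment uses 50 replicates of a 15-node class
over 3 days × 10 slots with well-functioning devices
(p_participate 0.8, p_detect_edge 0.9, p_miss 0.1) and
p_false_positive 0.1 — the regime where thresholding is the designed
remedy, and where the unthresholded full-window baseline is badly
polluted by false-positive edges; the coin-flip MCC calibration uses
1000 replicates against a fixed 20-node, density-0.5 GT; the full
60×5×16 grid is exercised on a 20-node study. A small reference table
of published classroom GT densities (ten class/direction combinations,
wave 1) ships in `socioscan.datasets` for calibration cross-checks.

## Known limitations

- The scanner-side `num_scans` definition undercounts scan effort for
  devices that scanned but detected nobody; with a scan-attempt log the
  definition could be widened (hook documented in `inference`).
- Accuracy on dense classroom GT networks rewards dense predictions;
  MCC should be preferred whenever GT density leaves the edge classes
  imbalanced.
- The paper-style schedule labels (S0–S49 for a 07:00–19:00
  quarter-hour day) imply endpoint-inclusive counting; real logs take
  their schedule from observed labels, and the generator uses the
  half-open 48-slot tiling. Only label arithmetic differs, not method.
- Edge-list export cannot represent isolates; GraphML round-trips the
  full node set.
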