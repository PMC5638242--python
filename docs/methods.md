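# Methods

## Model

`polyflow` reconstructs signaling pathways by routing imaginary flow from
experimental hits to transcriptional responses. Two hit classes — kinases
affected by synergizing inhibitors, and genetic modifiers from an siRNA
screen — are modeled as separate commodities in a shared-capacity
minimum-cost flow problem over a layered directed graph:

    source_k → hit nodes → protein–protein interactome → TFs → transcripts → sink

The LP minimizes Σ c_e·(Σ_k f_e,k) − γ·Σ_k F_k subject to per-commodity
conservation at interior nodes, per-commodity source-edge capacities, and a
shared cap Σ_k f_e,k ≤ u on every interactome, regulatory and sink edge.
Key modeling assumptions:

- **Edge cost** c = −ln(w) for confidence/match-score w ∈ (0, 1]. This is
  the probabilistic reading of "cost inversely related to confidence": path
  costs are additive, a perfectly confident edge is free, and the cheapest
  path is the most probable chain of independent interactions. A literal
  1/w mode is available (`cost_mode="inverse"`).
- **Capacity normalization.** Hit capacities arrive on incommensurate
  scales (percent activity change, Sensitivity Index, |log₂ FC|), so each
  commodity's source capacities are normalized to sum to 1 and sink
  capacities to sum to the number of commodities. This is the largest
  inferential choice in the package: it makes γ and the edge capacity
  meaningful across commodities, at the price of discarding the absolute
  magnitude difference between hit classes.
- **Undirected interactome edges** become antiparallel arc pairs sharing a
  single capacity pool (the sum of both directions is capped), preventing
  free two-way reuse of one interaction.
- **Transcript nodes are distinct from proteins** (`GENE_mRNA`), so a TF
  that is itself differentially expressed appears once as a signaling node
  and once as a sink.
- **Promiscuous cofactors** (EP300/P300, UBC by default) are removed from
  the interactome before graph construction; they touch so many partners
  that they carry no context-specific information.

Because γ rewards delivered flow linearly, total delivered flow is provably
non-decreasing in γ (verified over γ = 1..30 in the test suite), and the
network grows with γ.

## Parameters

| parameter | default | units / scale | rationale |
|---|---|---|---|
| `gamma` | 20 | dimensionless | flow-vs-cost tradeoff; chosen by leave-out jackknife over {14, 16, 18, 20, 22} |
| `edge_capacity` | 0.005 | normalized flow | shared per-edge cap; forces flow to spread over parallel paths |
| `flow_tolerance` | 1e-8 | normalized flow | reporting threshold, one order below the solver's feasibility tolerance |
| toxicity floor | 50 000 | luminescence units | vehicle-arm viability below this at any concentration marks an inhibitor toxic on its own |
| reduction threshold | 0.30 | fraction | drug-arm viability must fall > 30% below vehicle at a retained concentration |
| activity change | 50 | percent | kinase hit iff \|100 − activity\| > 50 under a hit inhibitor, and expressed |
| genetic filters | FDR < 0.05, \|SI−1\| > 0.3, survival ≥ 0.5 | — | modifier strength with an essentiality guard; validated hits get uniform capacity 3 |
| DE filters | q < 0.05, FC > 1.5, ≥ 0.1 FPKM, ΔFPKM ≥ 1 | — | significance, effect size, detectability, absolute-change guard against ratio artifacts |
| TSS window | 5 000 | bp | motif-match midpoint must lie within ± window of the gene's TSS |
| PWM threshold | 0.85 | normalized log-odds | per-matrix override supported in the PWM file (`CC threshold:` record) |
| `n_random` | 100 | networks/commodity | input randomizations for flow p-values |

## Dose-response fitting

Viability per arm is fit with the four-parameter type-1 Weibull curve
v(x) = c + (d − c)·exp(−exp(b·(ln x − ln e))) by bounded nonlinear least
squares, internally parameterized as (b, c, δ≥0, e) with d = c + δ so the
upper asymptote cannot cross the lower one. Initialization: d = max LU,
c = min LU, e = geometric-mean concentration, b = 1. Optimizer failure or
non-finite parameters mark the fit non-converged and exclude the inhibitor.
"Overlap" between arms — undefined in prose descriptions of such screens —
is operationalized per concentration as intersecting replicate min–max
ranges; overlapping concentrations are dropped before the reduction test.
Reductions are evaluated on the fitted curves at the tested concentrations
(raw-mean mode available), since the curves are what the model asserts
about the data.

## Regulatory layer

Peaks are merged as a union with bookended intervals coalesced (peak
fragmentation artifacts). Scanning scores every window on both strands with
min–max-normalized log-odds under a uniform background — a MATCH-style
score in [0, 1] — and keeps windows at or above the matrix threshold.
A TF→gene edge takes the best score among matches whose midpoint lies
within ± 5 kb of the TSS; the gene's strand does not restrict matches, and
one match may support several genes. Fisher-exact enrichment (one-sided,
"greater") contrasts DE against non-DE peak-bearing promoters per TF.

## Node significance

For each commodity the inputs are resampled uniformly without replacement
from the interactome node set (capacity multiset preserved, other
commodity's inputs fixed) and the LP re-solved `n_random` times. Within
every solved network a node's commodity flow is rank-normalized — rank
divided by the number of flow-carrying nodes, ties averaged — so networks
of different sizes are comparable. The p-value is (k+1)/(n+1) where k
counts null networks whose value reaches the real one; this cannot return
0, and its smallest attainable value at n = 100 is 1/101 ≈ 0.01. Nodes
never seen in the null get the sentinel −1; original inputs get NA.

Two calibration facts, both verified in the test suite, should guide
interpretation:

- **Per-node, the estimator is conservative.** When the "real" inputs are
  drawn from the same distribution as the null, P(p ≤ x) ≤ x for every x
  (exchangeability plus the +1 correction), with a point mass at p = 1
  from nodes whose flow is zero in the real network and tied at zero
  across the null.
- **Across nodes, defined p-values are not uniform.** Membership in the
  assessment table conditions on appearing in the real network; for
  peripheral nodes that appear rarely, this selects high flow values and
  shifts their p low, while nodes carrying only the other commodity's flow
  sit at p ≈ 1. The resulting cross-sectional distribution is bimodal —
  which is also the shape one should expect in candidate tables produced
  by this procedure on real data. Defined p-values should therefore be
  read as per-node tail probabilities, not compared against a uniform
  reference en masse.

The evidence score counts distinct hit inputs with a directed positive-flow
path to the node (the node itself excluded). Candidate selection requires a
defined p ≤ 0.05 in at least one commodity (−1/NA ignored, no
multiple-testing correction — selection is deliberately permissive at this
stage) and evidence ≥ 3. Evidence scores scale with interactome size: on a
12 000-node interactome top candidates reach scores of 40, whereas a
220-node synthetic scenario cannot produce deep upstream fan-in. The
enrichment test in the acceptance suite therefore applies the selection
rule at evidence ≥ 1, which is the scale-appropriate analogue for the
synthetic scenarios; the ≥ 3 default is untouched in the library.

Gamma is tuned by repeatedly dropping 20% of one commodity's inputs
(commodities alternate across repetitions), re-solving, and scoring edge
sets against the full-input network: sensitivity = fraction of original
edges recovered, specificity = fraction of leave-out edges present in the
original; the recommended γ maximizes their mean sum.

## Synthetic data

The generator emulates all six inputs with planted ground truth:

- **Interactome:** preferential attachment (Barabási–Albert, m = 2) over
  proteins + TFs — the simplest generator with both a heavy-tailed degree
  distribution and a connectivity guarantee; TF labels are scattered over
  the degree spectrum by permutation. Confidences are Beta(4, 2):
  right-skewed toward high confidence, as in curated interactomes.
- **Planted paths** run hit → intermediates → TF along edges upgraded to
  confidence ≥ 0.97, making the planted route the cheapest; each path TF
  gets planted DE targets, and every TF additionally gets decoy targets.
- **Screen:** 8 concentrations log-spaced over 3 decades, 2 replicates,
  Gaussian LU noise (sd 3 000 by default). Synergizers' drug arm follows a
  Weibull curve displaced ≥ 40% below vehicle at the top concentrations;
  non-synergizers share one curve in both arms (so their arms overlap and
  are excluded, as intended); toxic decoys dip below 50 000 LU in vehicle.
- **Genome/peaks/PWMs:** i.i.d. uniform nucleotides with each planted
  TF→gene edge realized as a peak near the target's TSS containing the
  TF's motif consensus on a random strand; PWMs are 8-mers with 0.94
  consensus probability per position. Background peaks sit outside every
  TSS window.
- **Tables:** planted DE genes and siRNA hits satisfy every filter; every
  decoy row violates at least one criterion, so zero-noise selection
  recovers truth exactly.

What the synthetic tests establish: the optimization, randomization and
selection machinery behave correctly on inputs with known structure. What
they do not establish: robustness to plate effects, batch structure,
correlated noise, annotation errors, or interactome ascertainment bias —
none of which the generator emulates. Scenario scale (hundreds of nodes) is
two orders below real interactomes; evidence scores and null-network
overlap behave accordingly.

## Numerical choices

- LP solved with HiGHS via `scipy.optimize.linprog`; variable order is
  fixed by sorted node/edge construction, so repeated runs are bit-identical
  and degeneracy is resolved deterministically by the solver.
- The strict SI-deviation inequality is applied with a 1e-9 epsilon so an
  SI of exactly 1.3 is excluded despite binary-float representation.
- Zero-probability PWM cells get a 1e-9 pseudo-probability before logs;
  windows containing ambiguous bases never match.
- A zero FPKM on one side of a DE comparison yields an infinite fold
  change; its capacity is capped (default 10) to keep sink capacities
  bounded. Rows with zero FPKM on both sides are skipped with a warning.
- Degenerate inputs: empty hit sets solve to the empty network; γ = 0
  ships no flow; unbounded LPs are impossible under finite capacities and
  asserted as such.

## Problem sizes used in the checks

The acceptance suite runs on scenarios of 200 proteins + 20 TFs, 100 genes
and 8 planted paths (the package's reference study size), with 100 input
randomizations per commodity; LP-oracle equivalence uses 50 random graphs
of ≤ 12 real nodes against exhaustive path enumeration; γ-monotonicity
uses 10 random instances over γ = 1..30. `scripts/acceptance.py` re-runs
the full pipeline at the reference size, including motif scanning and the
γ jackknife (6 repetitions per γ).

## Known limitations

- Whether the γ reward applies per commodity or to total flow is
  indistinguishable under the normalization used here; sink capacities are
  shared across commodities by default.
- The randomization null resamples input identities uniformly; it does not
  preserve the degree distribution of the hits, so hub-adjacent nodes may
  be slightly easier to reach under the null than under degree-matched
  resampling.
- SI is used literally as the genetic capacity (a `deviation` mode gives
  |SI − 1|); suppressors (SI < 0.7) therefore get *smaller* capacities than
  enhancers, which is a modeling convention, not a biological claim.
- No plate-effect or edge-well normalization in the screen module; the
  overlap rule is the only replicate-level QC.
- Symbols are upper-cased at load but not translated between identifier
  systems; unmapped symbols pass through verbatim.
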