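# Methods

## The data model

A key-event network is a directed acyclic graph of key events joined by
key event relationships.  Events carry a biological level of
organization (molecular, cellular, tissue, organ, individual,
population — the swim lane in a rendered diagram) and a role (MIE, KE,
AO).  KERs carry an innate five-level weight of evidence.  Assays attach
to events through typed measurement links (e.g. the peptide-reactivity
assay reports for covalent protein binding through cysteine depletion,
lysine depletion and an overall call); each link carries a
convincingness grade, and the assay itself a reliability grade and a
biological tier.  SAR prediction bases (typically structural alerts)
link to events, AOs or assays with their own grade pair.  Prediction
semantics are asymmetric: a basis that does not fire contributes
nothing; only models that emit explicit negative predictions produce
negative evidence.

Acyclicity is enforced at load time because the propagation semantics
below process events in topological order; every packaged network is
acyclic.  Key event groups may nest (a group member may itself be a
group).  A leaf event has at most one direct parent group; overlapping
membership is deferred to the ontology component, which permits multiple
parents per term.

## The calculus

The three lookup tables (grade pair → strength; same-direction 5×5;
opposing signed 5×5) ship as `data/calculus_tables.json` and are applied
literally, with three consequences worth knowing:

- **Sorted folding is normative.** The pairwise combination table is
  commutative and monotone but *not* associative (`(VL+VL)+M = H`,
  `VL+(VL+M) = M`), so argument lists are always sorted ascending and
  folded left.  Tests pin the witness.
- **Opposition is resolved through the signed table**, applied to the
  two per-side aggregates after cancelling equal-magnitude pairs in
  opposite directions.  Cancellation is greedy; equal-magnitude pairs
  are interchangeable, so the outcome is permutation invariant (tested
  exhaustively for small lists).
- **The opposing table is not monotone** in the usual sense
  (`−VH + H = −H` yet `−VH + M = −VH`).  It is implemented exactly as
  specified, without smoothing; downstream code must not assume
  monotonicity.

There are no irrefutable argument levels: the table's diagonal is
balanced everywhere, including `VH` against `VH`.

## Propagation paradigms

Events are processed in topological order; at each event local evidence
is merged with upstream contributions:

- **conservative** — any cause for concern wins.  Only Concern travels
  downstream: a negative assay is a local statement about that assay,
  not proof that the pathway is blocked, so NoConcern and Unknown create
  no downstream state.  Conflicted overall calls count as Concern (a
  deliberate, conservative choice; disagreement is itself a signal).
- **tiered** — the highest biological tier with informative evidence
  decides, merged conservatively within the tier.  The default ranking
  is human observation > in vivo > in vitro = in chemico > in silico and
  is configurable (`tier_rank=`), since the reliability of human
  observational data is itself debatable.  Upstream-propagated Concern
  enters at a pseudo-tier below in silico: it is inferred rather than
  measured, so any local measurement or prediction overrules it, while
  events with no local evidence still inherit it.
- **calculus** — every input becomes a signed strength: assay calls via
  (link convincingness × assay reliability), predictions via the basis
  grades transmitted through the prediction–event relationship's own
  grade pair, and Conflicted calls as a weak (+VL) argument for concern.
  Upstream signed conclusions are transmitted through their KER (lower
  value wins) and resolved first into a single "likelihood of preceding
  events" argument before joining the local pool, so a long chain of
  upstream events speaks with one voice rather than once per edge.

Measurement-level calls feed an event only through the assay's overall
call when one is recorded; otherwise the conservative merge of the
event-linked measurement calls stands in.

The expert-weighted pie-chart summary (`weighted_score`) classifies the
weight-normalised mean score against a symmetric equivocation band of
±0.15.  The band is a package choice (configurable): it is wide enough
that re-weighting the same three arguments from 75:23:2 to 50:40:10
changes the overall call, which is the behaviour the display is meant to
illustrate; no finer precision is claimed.

## Similarity and concordance

The default fingerprint hashes linear atom/bond paths of 1–7 atoms over
the hydrogen-suppressed molecular graph (aromaticity-aware, canonical
under path reversal, SHA-1 → 32-bit features).  It is deliberately
simple and fully documented; the scheme registry accepts replacements
(e.g. a toolkit's circular fingerprints), because the substantive point
is that similarity is measure dependent.  The alert-based biological
fingerprint uses the set of fired prediction bases.  Similarity is the
Tanimoto coefficient, defined as 1 for two empty fingerprints.

Assay-call "correlation" is the phi coefficient of the 2×2
Positive/Negative table, equal to Pearson on 0/1 coding (tested against
that oracle on 500 random tables).  Conflicted and missing calls are
excluded pairwise as non-informative.  Cells are **Masked** — never set
to 0 — when a table margin is zero or fewer than `min_n` (default 5)
informative pairs remain; conditioning on an assay removes its variance,
so its own row and column are always Masked in conditioned matrices.
Whether graded alternatives (Pearson on ordinal calls, concordance
fraction) would behave differently is an open question; phi was chosen
for its exact binary semantics.

The next-assay ranking scores each unmeasured assay on the paths to the
target event by its strongest |phi| against the target-linked assays,
computed over the query's similarity neighborhood, further conditioned
on each of the query's own calls whenever the conditioned subset keeps
at least `min_n` compounds.  Candidates whose concordance is everywhere
masked fall back to fewest-KER-hops ordering; ties break by larger n,
then assay id.

## Curation rules

Raw call text normalises through a case-insensitive synonym table
({positive, active, pos, +} → Positive, etc.); unmapped text is rejected
with the offending string rather than guessed at — the only operational
form of "unreliable results were excluded" implemented here.  Repeated
results under one assay definition (assay id plus the canonicalized
variable map, where variable values are case-folded and token-sorted so
"Rat S9" ≡ "S9 Rat") aggregate to a single overall call; any
disagreement yields Conflicted.  Structure standardization (valency
checks, tautomer canonicalization, salt stripping) is out of scope:
SMILES are accepted as given.

## Synthetic data

The fixture catalog encodes the worked examples the package is designed
around: the five-event skin-sensitization AOP with its seven assays and
one alert; a two-MIE reproductive-toxicity network; a genotoxicity
network (Ames → inherited DNA mutation → genetic instability / cancer);
the retinoid X receptor carcinogenicity network with a three-member p38
MAPK group and a nested two-member proliferation group (sub-KE names
marked synthetic where the published labels stop); an oestrogen-receptor
is-a ontology with an 18-assay grouping; a full linalool evidence
record; and a 28-compound panel around 2,4-dihydroxyaniline.  Fixture
files are frozen by checksum in the tests.

The panel's calls are drawn by `random_calls`: latent standard normals
thresholded at zero, so planted phi *t* maps exactly to latent
correlation ρ = sin(πt/2) and the empirical phi converges to the target
(tested within ±0.1 at n = 2000 for targets −0.8, 0, 0.8).  The
scenario's pairwise targets come from a one-factor loading model
(reactivity assays loading ≈0.9, cell-based assays ≈0.65), which keeps
the implied latent matrix positive semidefinite by construction.  The
panel is small and its chemistry hand-picked; it does not emulate the
"lumpiness" of real tested chemical space, class imbalance of real call
tables, or inter-laboratory variance, so passing tests demonstrate the
machinery, not field performance on real datasets.  `random_ken`
generates layered DAGs (first layer MIEs, last layer AOs, every
non-source with a parent) for property testing.

Problem sizes throughout (2000 compounds for concordance recovery, 50
generator seeds, 500 oracle tables) were chosen as the smallest at which
the stochastic checks are comfortably stable.

## Known limitations

- Undercutting ("gotcha") arguments and numeric Bayesian belief
  propagation are out of scope by design.
- Hazard only: no dose–response, exposure or risk; human-relevance
  discounting appears only as provenance text.
- The layered DOT/GraphML export aims at determinism, not layout
  aesthetics; interactive rendering is a GUI concern.
- OBO/OWL ontology import is an extension point; the TSV format covers
  the packaged examples.  Event ordering cannot be captured in the is-a
  ontology and no attempt is made to encode KER sequence there.
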