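# aopnet

Key-event networks for predictive toxicology: adverse outcome pathway
(AOP) building blocks — molecular initiating events (MIEs), key events
(KEs), key event relationships (KERs) and adverse outcomes (AOs) —
combined into networks, augmented with assay knowledge and
structure–activity (SAR) prediction bases, and used to propagate
compound-level hazard evidence to adverse outcomes with a categorical
weight-of-evidence reasoning calculus.

The package is aimed at computational toxicologists and cheminformaticians
who want to answer, for a compound of interest:

1. **What do compounds like mine do?** — fingerprint/Tanimoto
   neighborhoods and per-assay activity profiles (`aopnet.similarity`).
2. **Given this assay result, what AOs should I be worried about?** —
   downstream closure of the events an assay reports for
   (`aopnet.propagation.alerted_aos`).
3. **What assay should I run next?** — assay-call concordance (phi)
   among chemically similar compounds, conditioned on the compound's
   existing calls (`aopnet.concordance`, `aopnet.propagation.suggest_next`).

## The reasoning calculus

Evidence at an event is expressed as arguments *for* or *against* a cause
for concern.  Each argument carries two three-valued grades — the
intrinsic **convincingness** of the line of argument and the
**reliability** (consistency) of the evidence behind it — which reduce to
a five-valued **strength** `VL < L < M < H < VH` by a 3×3 lookup:

|            | Large conv. | Medium | Small |
|------------|-------------|--------|-------|
| **Large rel.**  | VH | H | M |
| **Medium rel.** | H  | M | L |
| **Small rel.**  | M  | L | VL |

Same-direction strengths combine through a 5×5 table in which weak
arguments reinforce each other only so far (`M + VL = M`; lists are
sorted ascending and folded left because the table is not associative:
`(VL+VL)+M = H` but `VL+(VL+M) = M`).  Opposing strengths resolve through
a signed 5×5 table whose diagonal is balanced — there are no irrefutable
arguments.  Transmission along a KER takes the lower of the argument and
the connection strength.  The conclusion at each event is one of 11
signed positions `{−VH … −VL, 0, +VL … +VH}`.

Alongside the calculus sit two simpler categorical paradigms:
**conservative** (any cause for concern wins and cascades downstream)
and **tiered** (measured results overrule predictions: human observation
> in vivo > in vitro = in chemico > in silico).

## Worked example

Propagating the packaged evidence record for (+/−)-linalool (peptide
reactivity and keratinocyte assays negative; LLNA and human observation
positive; one SAR alert firing) through the covalent-protein-binding
skin-sensitization AOP:

```python
from aopnet import fixture, propagate

fx = fixture("linalool_evidence")
for paradigm in ("conservative", "calculus"):
    result = propagate(fx.network, fx.evidence, paradigm)
    print(paradigm)
    for eid in fx.network.events:
        signed = f"  {result.signed[eid]}" if eid in result.signed else ""
        print(f"  {eid:28s} {result.states[eid].value}{signed}")
```

prints

```
conservative
  covalent_protein_binding     NoConcern
  keratinocyte_activation      NoConcern
  dendritic_cell_activation    Unknown
  t_cell_activation            Concern
  skin_sensitization           Concern
calculus
  covalent_protein_binding     NoConcern  -VeryHigh
  keratinocyte_activation      NoConcern  -VeryHigh
  dendritic_cell_activation    NoConcern  -Medium
  t_cell_activation            Concern  +VeryHigh
  skin_sensitization           Concern  +VeryHigh
```

Early events are green (the assays that probe them are negative), late
events red (in vivo and human evidence positive) — the inconsistency
itself is informative: the mechanism runs through an oxidation product
the early assays do not see.  Note the two paradigms disagree at the
dendritic-cell event: conservatively it is untested (grey), while the
calculus carries the upstream negative evidence forward as `−M`.

The same queries are available from the shell:

```bash
aopnet fixtures                       # list packaged example networks
aopnet propagate --paradigm tiered    # CSV per-event report
aopnet alerted-aos --source ames      # AOs alerted by a positive Ames
aopnet similar --cutoff 0.4           # Tanimoto neighborhood
aopnet correlate --min-n 5            # phi heat-map layers as CSV
aopnet suggest-next --cutoff 0.3      # next-assay ranking
aopnet export --out net.dot           # deterministic DOT rendering
```

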