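# unguis

Quantitative tools for diagnosing primate unguis form (nail, claw,
grooming claw) from distal-phalanx shape, placing fossil feet among
extant primate groups by pedal proportions, and analysing morphological
character matrices with ordered-character maximum parsimony.

## The problem

Prosimian primates carry a *grooming claw* on the second pedal digit;
most anthropoids carry a nail.  Whether an Eocene fossil primate had one
bears directly on early primate relationships — but a fossil is a sample
of one, and the raw measurements behind published comparative samples are
usually unavailable.  This package implements the standard quantitative
workflow for that situation:

- **`unguis.phalanx`** — geometric-mean size standardization of nine
  phalanx measurements, shape ratios, correlation-matrix PCA with convex
  hull assignment, and classification of single fossils against extant
  group summaries via the Sokal–Rohlf single-specimen t-test
  `t = (x − x̄)/(s·√((n+1)/n))`, df = n − 1.
- **`unguis.foot`** — six pedal indices (pp4/mt4, mt1/mt2, mt3/mt4,
  mt4/mt5, pp2/pp5, pp3/pp4), Welch/Mann–Whitney and
  ANOVA/Kruskal–Wallis/Tukey batteries, and linear discriminant analyses
  of GM-standardized element lengths with jackknife (leave-one-out)
  validation.
- **`unguis.parsimony`** — NEXUS character matrices with polymorphism and
  missing data, Fitch (unordered) and Farris interval (ordered, cost
  |i−j|) tree lengths, exhaustive and branch-and-bound searches over all
  (2n−5)!! topologies, ensemble statistics TL, CI = Σm/Σs, HI = 1 − CI,
  RI = (Σg−Σs)/(Σg−Σm), RC = CI·RI, strict/majority consensus trees, and
  replayable published matrix revisions.
- **`unguis.simulate` / `unguis.tables`** — seeded generators with the
  statistical structure the analyses assume, and the published summary
  tables packaged as typed fixtures.

## Worked example

Classify the fossil second-digit distal phalanx against the published
extant nail and grooming-claw baselines:

```python
from unguis import tables
from unguis.phalanx import classify_fossil

row = tables.table_fossil_phalanges().loc["143612-03 (dp2)"]
report = classify_fossil(
    {"specimen_id": "dp2", "FSA": row.FSA, "VFL_TPL": row.VFL_TPL,
     "SH14_SH34": row.SH14_SH34, "SW34_TPL": row.SW34_TPL},
    tables.unguis_baselines(),
)
print(report.verdict)
print(report.table.round(2)[["t", "df", "p"]])
```

prints

```
grooming-like
                        t  df    p
variable  group
FSA       ungular   -3.01  20 0.01
          grooming  -1.08   9 0.31
VFL_TPL   ungular   -3.49  20 0.00
          grooming   0.51   9 0.62
SH14_SH34 ungular    4.73  20 0.00
          grooming   0.47   9 0.65
SW34_TPL  ungular    1.21  20 0.24
          grooming   3.43   9 0.01
```

Each `t` compares the fossil with one extant group; the smaller |t| per
variable marks the more similar group.  This phalanx is nearer the
grooming-claw group in facet–shaft angle (dorsally canted shaft),
relative volar length (short volar process) and shaft tapering — the
three traits that jointly diagnose a grooming claw — hence the
`grooming-like` verdict, even though its apical tuft width (SW34/TPL)
remains nail-like.

The `examples/` directory holds one short script per capability
(grooming-claw diagnosis, pedal proportions and DFA, parsimony search
and consensus, matrix revision replay); each prints its results with a
line on what the numbers mean.

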