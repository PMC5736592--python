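"""Build one grooming-rate network by hand and read off the five metrics.

Four adults in one group-year: A grooms B a lot, B reciprocates a little,
A also grooms C, and D is never seen grooming. The printed rates are
seconds of grooming per combined observation hour of the dyad; the
metrics quantify how connected (or isolated) each individual is.
"""

import pandas as pd

from socisol import (
    DemographyTables,
    assemble_group_year,
    betweenness,
    build_rate_matrix,
    clustering_coefficient,
    eigenvector_centrality,
    instrength,
    outstrength,
)
from socisol.dataio import validate_tables

tables = validate_tables(DemographyTables(
    individuals=pd.DataFrame({
        "id": ["A", "B", "C", "D"],
        "sex": ["F", "F", "M", "M"],
        "birth_year": [2000, 1998, 1995, 2003],
        "mother_id": [None] * 4,
        "natal_group": ["G"] * 4,
    }),
    membership=pd.DataFrame({
        "id": ["A", "B", "C", "D"], "group": ["G"] * 4,
        "year": [2013] * 4, "full_year": [True] * 4,
    }),
    grooming=pd.DataFrame({
        "actor": ["A", "B", "A"], "recipient": ["B", "A", "C"],
        "group": ["G"] * 3, "year": [2013] * 3,
        "seconds": [120.0, 30.0, 60.0],
    }),
    effort=pd.DataFrame({
        "id": ["A", "B", "C", "D"], "group": ["G"] * 4, "year": [2013] * 4,
        "hours_observed": [4.0, 6.0, 5.0, 5.0],
    }),
    agonistic=pd.DataFrame(columns=["winner", "loser", "group", "year", "count"]),
    pedigree=pd.DataFrame({"id": ["A", "B", "C", "D"],
                           "mother_id": [None] * 4, "father_id": [None] * 4}),
))

net = build_rate_matrix(assemble_group_year(tables, "G", 2013))
print("rate A->B (120 s over 4+6 h):", round(net.W[net.index("A"), net.index("B")], 2), "s/h")

print("\nid  instrength  outstrength  betweenness  clustering  eigenvector")
bc = betweenness(net)
cc = clustering_coefficient(net)
ev = eigenvector_centrality(net)
for i in net.ids:
    c = "None " if cc[i] is None else f"{cc[i]:.2f} "
    print(f"{i}   {instrength(net, i):9.2f}  {outstrength(net, i):10.2f}"
          f"  {bc[i]:10.2f}  {c:>9}  {ev[i]:10.3f}")

print(
    "\nD gives and receives nothing (strengths 0) - socially isolated.\n"
    "B and C have a single partner each, so their clustering coefficient\n"
    "is undefined (None); A's betweenness of 1 counts the single shortest\n"
    "path (B -> A -> C) that connects two other animals through it."
)
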