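"""Ancestral chromosome-region adjacencies and clade synapomorphies.

Encodes the observed arrangements of labelled chromosomal regions
(A1..D2, E) in representative magnoliid, monocot, eudicot and ANA-grade
genomes, reconstructs ancestral adjacency patterns by parsimony on the
species tree, and asks which adjacencies are shared derived characters of
the magnoliid + monocot clade.
"""

from paleosyn import extract_adjacencies, find_synapomorphies, fitch_ancestral, read_tree
from paleosyn.rearrange import RegionCatalog

magnoliid_like = {
    "c1": [("A1", "+"), ("A2", "+"), ("B1", "+"), ("B2", "+")],
    "c2": [("C1", "+"), ("C2", "+")],
    "c3": [("D1", "+"), ("D2", "+")],
    "c4": [("E", "+")],
}
eudicot_like = {
    "c1": [("A1", "+"), ("A2", "+"), ("C1", "+")],
    "c2": [("B1", "+"), ("B2", "+")],
    "c3": [("D1", "+"), ("D2", "+"), ("C2", "+")],
    "c4": [("E", "+")],
}
ana_like = {
    "c1": [("A1", "+"), ("A2", "+"), ("C1", "+")],
    "c2": [("B1", "+"), ("B2", "+"), ("C2", "+")],
    "c3": [("D1", "+"), ("D2", "+")],
    "c4": [("E", "+")],
}
labels = ["A1", "A2", "B1", "B2", "C1", "C2", "D1", "D2", "E"]

catalog = RegionCatalog.from_arrangements(
    {
        "magnoliid": magnoliid_like,
        "monocot": magnoliid_like,
        "eudicot": eudicot_like,
        "nymphaea": ana_like,
        "amborella": ana_like,
    }
)
patterns = {sp: extract_adjacencies(catalog, sp) for sp in catalog.species()}
tree = read_tree(
    "(amborella,(nymphaea,((magnoliid,monocot)magmono,eudicot)meso)nonamb)root;"
)
recon = fitch_ancestral(patterns, tree)

for node in ("magmono", "meso", "root"):
    groups = recon.node_patterns[node].linear_groups(labels)
    print(f"{node}: " + ", ".join("-".join(g) for g in groups))
syn = find_synapomorphies(recon, "magmono")
print("magnoliid+monocot synapomorphies:")
for adj in sorted(syn, key=sorted):
    (la, ea), (lb, eb) = sorted(adj)
    print(f"  {la}.{ea} -- {lb}.{eb}")
# The A2-B1 join and the C1-C2 join arise on the magnoliid+monocot stem and
# are absent in eudicots and the ANA grade: rare genomic changes supporting
# a magnoliid + monocot clade.
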