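import itertools

import pytest

from paleosyn.model import GenomeTable
from paleosyn.rearrange import RegionCatalog, extract_adjacencies


def make_genome(species: str, chrom_sizes: dict[str, int], family_offset: int = 0):
    """Toy genome with ``n`` genes per chromosome at [1000i, 1000i+500)."""
    records = []
    fam = family_offset
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            records.append((chrom, 1000 * i, 1000 * i + 500, "+", f"{species}_{chrom}_{i}", f"F{fam}"))
            fam += 1
    return GenomeTable.from_records(species, records)


# Worked example: region arrangements of the major angiosperm clades.
MAGNOLIID_LIKE = {
    "c1": [("A1", "+"), ("A2", "+"), ("B1", "+"), ("B2", "+")],
    "c2": [("C1", "+"), ("C2", "+")],
    "c3": [("D1", "+"), ("D2", "+")],
    "c4": [("E", "+")],
}
EUDICOT_LIKE = {
    "c1": [("A1", "+"), ("A2", "+"), ("C1", "+")],
    "c2": [("B1", "+"), ("B2", "+")],
    "c3": [("D1", "+"), ("D2", "+"), ("C2", "+")],
    "c4": [("E", "+")],
}
ANA_LIKE = {
    "c1": [("A1", "+"), ("A2", "+"), ("C1", "+")],
    "c2": [("B1", "+"), ("B2", "+"), ("C2", "+")],
    "c3": [("D1", "+"), ("D2", "+")],
    "c4": [("E", "+")],
}
REGION_LABELS = ["A1", "A2", "B1", "B2", "C1", "C2", "D1", "D2", "E"]
ANGIOSPERM_TREE = "(amborella,(nymphaea,((magnoliid,monocot)magmono,eudicot)meso)nonamb)root;"


@pytest.fixture
def angiosperm_patterns():
    catalog = RegionCatalog.from_arrangements(
        {
            "magnoliid": MAGNOLIID_LIKE,
            "monocot": MAGNOLIID_LIKE,
            "eudicot": EUDICOT_LIKE,
            "nymphaea": ANA_LIKE,
            "amborella": ANA_LIKE,
        }
    )
    return {sp: extract_adjacencies(catalog, sp) for sp in catalog.species()}


def all_pairs(genes):
    return [(min(a, b), max(a, b)) for a, b in itertools.combinations(genes, 2)]
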