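"""Reference census data for the *B. thetaiotaomicron* regulon collection.

Packages the published census of SusR-like and HTCS regulators, the
monosaccharide-utilization regulons, the polysaccharide/sugar-utilization
(PSU) network category counts, and the global Crp-like palindrome consensus.
Counting is by table row, not by distinct regulon name (HTCS_Rgu-1 and
HTCS_Rgu-2 each span two paralogous regulators and appear on two rows each).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources

VALID_CLASSES = {"HTCS", "SusR_like"}

#: consensus of the global Crp-like regulator's 22-bp palindromic site
#: (lowercase w = A/T, lowercase n = any base)
CRP_CONSENSUS = "wwwTATGTTnTAnAACATAwww"


class FixtureError(ValueError):
    """Packaged reference data failed schema validation."""


@dataclass
class RegulatorRecord:
    locus_tag: str
    regulator_class: str   # HTCS | SusR_like
    regulon_name: str      # empty if no regulon was reconstructed
    n_orthologs: int
    substrate: str


@dataclass
class MonosaccharideRegulonRecord:
    regulator_name: str
    locus_tag: str
    n_orthologs: int
    pathway: str
    family: str


@dataclass
class NetworkCategoryCounts:
    psu_network: dict[str, int]
    novel_genes: dict[str, int]
    model_seed_overlap: dict[str, int]
    curated_model_overlap: dict[str, int]

    def category_sum(self, section: str) -> int:
        d = getattr(self, section)
        return sum(v for k, v in d.items() if k != "total")

    def total(self, section: str) -> int:
        return getattr(self, section)["total"]


def _data_text(name: str) -> str:
    return (resources.files("regulonkit") / "data" / name).read_text()


def load_table1() -> list[RegulatorRecord]:
    """SusR-like and HTCS regulator census."""
    rows = list(csv.DictReader(_data_text("table1_regulators.tsv").splitlines(),
                               delimiter="\t"))
    records = []
    seen = set()
    for r in rows:
        cls = r["class"]
        if cls not in VALID_CLASSES:
            raise FixtureError(f"{r['locus_tag']}: unknown class {cls!r}")
        if r["locus_tag"] in seen:
            raise FixtureError(f"duplicate locus_tag {r['locus_tag']}")
        seen.add(r["locus_tag"])
        n = int(r["n_orthologs"])
        if n < 0:
            raise FixtureError(f"{r['locus_tag']}: negative ortholog count")
        records.append(RegulatorRecord(
            locus_tag=r["locus_tag"], regulator_class=cls,
            regulon_name=r["regulon_name"] or "",
            n_orthologs=n, substrate=(r.get("substrate") or "").strip()))
    return records


def load_table2() -> list[MonosaccharideRegulonRecord]:
    """Regulons controlling cytoplasmic monosaccharide utilization."""
    rows = list(csv.DictReader(
        _data_text("table2_monosaccharide_regulons.tsv").splitlines(),
        delimiter="\t"))
    records = []
    for r in rows:
        if not r["family"]:
            raise FixtureError(f"{r['regulator_name']}: empty family")
        records.append(MonosaccharideRegulonRecord(
            regulator_name=r["regulator_name"], locus_tag=r["locus_tag"],
            n_orthologs=int(r["n_orthologs"]), pathway=r["pathway"],
            family=r["family"]))
    return records


def load_network_counts() -> NetworkCategoryCounts:
    """Category counts of the reconstructed PSU metabolic/regulatory network."""
    payload = json.loads(_data_text("network_counts.json"))
    counts = NetworkCategoryCounts(**payload)
    for section in ("psu_network", "novel_genes", "model_seed_overlap",
                    "curated_model_overlap"):
        d = getattr(counts, section)
        if any(v < 0 for v in d.values()):
            raise FixtureError(f"{section}: negative count")
        if "total" not in d:
            raise FixtureError(f"{section}: missing total")
    return counts


def crp_consensus() -> str:
    """The packaged 22-bp Crp-like palindrome consensus, verbatim."""
    return CRP_CONSENSUS


def count_by_class(records: list[RegulatorRecord]) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in records:
        out[r.regulator_class] = out.get(r.regulator_class, 0) + 1
    return out


def count_named(records: list[RegulatorRecord],
                regulator_class: str | None = None) -> int:
    """Rows with a reconstructed (named) regulon, counted by row."""
    return sum(1 for r in records
               if r.regulon_name
               and (regulator_class is None
                    or r.regulator_class == regulator_class))
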