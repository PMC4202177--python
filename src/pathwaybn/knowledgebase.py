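"""Relation/reaction knowledgebase built from KGML reference pathway maps.

KEGG-style reference pathway maps encode a metabolic pathway as *entries*
(nodes, labelled with KEGG Orthology (KO) identifiers for enzymes or with
compound identifiers for metabolites) connected by *relations* (e.g. ECrel,
PPrel) and *reactions*.  Harvesting every relation/reaction from a set of
maps, regardless of which pathway it came from, yields a knowledgebase of
KO-level edges.  Projected through a gene→KO assignment table this becomes
the whitelist of gene-gene edges that constrains Bayesian-network structure
search.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

KO_PATTERN = re.compile(r"^K\d{5}$")


class NodeKind(Enum):
    ENZYME = "enzyme"
    COMPOUND = "compound"
    MAP = "map"
    OTHER = "other"


@dataclass(frozen=True)
class EntryNode:
    """A node of a pathway map: an enzyme (≥1 KO id), a compound, or other."""

    entry_id: str
    ko_ids: frozenset[str]
    node_kind: NodeKind
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if self.node_kind is NodeKind.ENZYME and not self.ko_ids:
            raise ValueError(f"enzyme entry {self.entry_id!r} has no KO ids")
        if self.node_kind is NodeKind.COMPOUND and self.ko_ids:
            raise ValueError(f"compound entry {self.entry_id!r} carries KO ids")


@dataclass(frozen=True)
class KnowledgeRecord:
    """One relation or reaction: KO sets upstream/downstream plus compounds."""

    upstream: frozenset[str]
    downstream: frozenset[str]
    record_type: str
    compounds: frozenset[str] = frozenset()
    source_map: str = ""

    def __post_init__(self) -> None:
        if not self.upstream or not self.downstream:
            raise ValueError("knowledge record needs non-empty upstream and downstream")

    def ko_pairs(self) -> set[tuple[str, str]]:
        """Ordered (upstream, downstream) KO pairs: the cartesian expansion."""
        return {(u, d) for u in self.upstream for d in self.downstream}


@dataclass
class PathwayMap:
    """A parsed KGML pathway map."""

    map_id: str
    entries: list[EntryNode]
    relations: list[KnowledgeRecord]
    reactions: list[KnowledgeRecord]
    n_skipped: int = 0

    @property
    def records(self) -> list[KnowledgeRecord]:
        return self.relations + self.reactions

    def enzyme_entries(self) -> list[EntryNode]:
        return [e for e in self.entries if e.node_kind is NodeKind.ENZYME]


@dataclass
class GeneKOMap:
    """Forward gene→KO-set mapping with a consistent KO→gene reverse index."""

    entries: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, kos in self.entries.items():
            if not kos:
                raise ValueError(f"gene {gene!r} maps to no KO")
            bad = [k for k in kos if not KO_PATTERN.match(k)]
            if bad:
                raise ValueError(f"gene {gene!r} has malformed KO ids: {bad}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self.entries[gene]

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def ko_to_genes(self) -> dict[str, set[str]]:
        rev: dict[str, set[str]] = defaultdict(set)
        for gene, kos in self.entries.items():
            for ko in kos:
                rev[ko].add(gene)
        return dict(rev)


@dataclass
class RelationKnowledgebase:
    """All KnowledgeRecords from a set of maps plus an ordered KO-pair index."""

    records: list[KnowledgeRecord]
    ko_pair_index: dict[tuple[str, str], list[KnowledgeRecord]]

    def has_pair(self, upstream_ko: str, downstream_ko: str) -> bool:
        return (upstream_ko, downstream_ko) in self.ko_pair_index

    def records_for_pair(self, upstream_ko: str, downstream_ko: str) -> list[KnowledgeRecord]:
        return self.ko_pair_index.get((upstream_ko, downstream_ko), [])

    def query(self, kos: Iterable[str]) -> list[KnowledgeRecord]:
        """Records whose upstream and downstream both intersect the KO set."""
        koset = set(kos)
        return [r for r in self.records if r.upstream & koset and r.downstream & koset]


def _split_kos(name_attr: str) -> frozenset[str]:
    kos = set()
    for token in name_attr.split():
        token = token.removeprefix("ko:")
        if KO_PATTERN.match(token):
            kos.add(token)
    return frozenset(kos)


def _entry_from_element(elem: ET.Element) -> EntryNode:
    entry_id = elem.get("id", "")
    entry_type = elem.get("type", "other")
    name = elem.get("name", "")
    kos = _split_kos(name)
    if entry_type == "compound":
        compound = name.split()[0].removeprefix("cpd:") if name else None
        return EntryNode(entry_id, frozenset(), NodeKind.COMPOUND, compound)
    if entry_type == "map":
        return EntryNode(entry_id, frozenset(), NodeKind.MAP)
    if kos:
        return EntryNode(entry_id, kos, NodeKind.ENZYME)
    return EntryNode(entry_id, frozenset(), NodeKind.OTHER)


def parse_kgml(document: str) -> PathwayMap:
    """Parse a KGML document into a :class:`PathwayMap`.

    Relations whose endpoints reference unknown entry ids, or entries without
    KO numbers (map links, compounds), are skipped with a logged warning and
    counted in ``n_skipped``.

    Raises
    ------
    ValueError
        If the XML is malformed (message names the offending line).
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ValueError(f"malformed KGML at line {line}, column {col}: {exc}") from exc

    map_id = root.get("name", root.get("title", "unknown"))
    entries = [_entry_from_element(e) for e in root.findall("entry")]
    by_id = {e.entry_id: e for e in entries}

    skipped = 0
    relations: list[KnowledgeRecord] = []
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1", ""), rel.get("entry2", "")
        rel_type = rel.get("type", "relation")
        up, down = by_id.get(e1), by_id.get(e2)
        if up is None or down is None:
            logger.warning("map %s: relation %s->%s references unknown entry; skipped",
                           map_id, e1, e2)
            skipped += 1
            continue
        if not up.ko_ids or not down.ko_ids:
            logger.warning("map %s: relation %s->%s endpoint has no KO ids; skipped",
                           map_id, e1, e2)
            skipped += 1
            continue
        compounds = set()
        for sub in rel.findall("subtype"):
            if sub.get("name") == "compound":
                centry = by_id.get(sub.get("value", ""))
                if centry is not None and centry.compound_id:
                    compounds.add(centry.compound_id)
        relations.append(KnowledgeRecord(up.ko_ids, down.ko_ids, rel_type,
                                         frozenset(compounds), map_id))

    reactions: list[KnowledgeRecord] = []
    for rxn in root.findall("reaction"):
        owner = by_id.get(rxn.get("id", ""))
        if owner is None or not owner.ko_ids:
            logger.warning("map %s: reaction %s has no KO-bearing entry; skipped",
                           map_id, rxn.get("id"))
            skipped += 1
            continue
        compounds = set()
        for tag in ("substrate", "product"):
            for c in rxn.findall(tag):
                cid = c.get("name", "").removeprefix("cpd:")
                if cid:
                    compounds.add(cid)
        reactions.append(KnowledgeRecord(owner.ko_ids, owner.ko_ids, "reaction",
                                         frozenset(compounds), map_id))

    return PathwayMap(map_id, entries, relations, reactions, n_skipped=skipped)


def build_knowledgebase(maps: list[PathwayMap],
                        exclude_maps: Iterable[str] = ()) -> RelationKnowledgebase:
    """Pool records from all maps and index every ordered KO pair.

    ``exclude_maps`` drops records whose source map id is listed, e.g. to keep
    the target organism's own pathways out of the knowledge used to predict
    them.  Duplicate records across maps are all retained, but the pair index
    collapses them onto the same key.
    """
    if not maps:
        raise ValueError("need at least one pathway map")
    excluded = set(exclude_maps)
    records: list[KnowledgeRecord] = []
    index: dict[tuple[str, str], list[KnowledgeRecord]] = defaultdict(list)
    for pmap in maps:
        if pmap.map_id in excluded:
            continue
        for rec in pmap.records:
            records.append(rec)
            for pair in rec.ko_pairs():
                index[pair].append(rec)
    return RelationKnowledgebase(records, dict(index))


def load_gene_ko_map(table: str, sep: str = "\t") -> GeneKOMap:
    """Parse a two-column gene→KO table (one row per assignment, no header).

    A gene appearing on several rows accumulates all its KO ids, as in the
    output of homology-based annotation servers.
    """
    entries: dict[str, set[str]] = defaultdict(set)
    for lineno, raw in enumerate(table.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split(sep) if sep in line else line.split()
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"gene→KO table row {lineno}: expected two columns, got {raw!r}")
        entries[fields[0]].add(fields[1])
    return GeneKOMap({g: frozenset(k) for g, k in entries.items()})


def allowed_gene_edges(kb: RelationKnowledgebase, komap: GeneKOMap,
                       genes: set[str]) -> set[tuple[str, str]]:
    """Gene-level whitelist: ordered pairs supported by some indexed KO pair.

    An edge (g_u, g_d) is allowed when a KO of g_u and a KO of g_d form an
    ordered pair in the knowledgebase index.  Self-pairs are never emitted,
    but two distinct genes sharing a KO with an indexed self-KO relation do
    yield cross-gene edges in both directions.
    """
    missing = sorted(g for g in genes if g not in komap)
    if missing:
        raise KeyError(f"genes absent from gene→KO map: {missing}")
    ko_to_genes: dict[str, set[str]] = defaultdict(set)
    for g in genes:
        for ko in komap[g]:
            ko_to_genes[ko].add(g)
    edges: set[tuple[str, str]] = set()
    for (ku, kd) in kb.ko_pair_index:
        for gu in ko_to_genes.get(ku, ()):
            for gd in ko_to_genes.get(kd, ()):
                if gu != gd:
                    edges.add((gu, gd))
    return edges


def knowledgebase_to_tsv(kb: RelationKnowledgebase) -> str:
    """Serialize records as TSV: upstream KOs, downstream KOs, type, compounds, map."""
    lines = ["upstream\tdownstream\ttype\tcompounds\tsource_map"]
    for r in kb.records:
        lines.append("\t".join([
            ",".join(sorted(r.upstream)),
            ",".join(sorted(r.downstream)),
            r.record_type,
            ",".join(sorted(r.compounds)),
            r.source_map,
        ]))
    return "\n".join(lines) + "\n"


def knowledgebase_from_tsv(text: str) -> RelationKnowledgebase:
    records = []
    lines = text.strip().splitlines()
    for raw in lines[1:]:
        up, down, rtype, comps, src = (raw.split("\t") + [""] * 5)[:5]
        records.append(KnowledgeRecord(
            frozenset(up.split(",")), frozenset(down.split(",")), rtype,
            frozenset(c for c in comps.split(",") if c), src))
    index: dict[tuple[str, str], list[KnowledgeRecord]] = defaultdict(list)
    for rec in records:
        for pair in rec.ko_pairs():
            index[pair].append(rec)
    return RelationKnowledgebase(records, dict(index))


def pair_index_to_tsv(kb: RelationKnowledgebase) -> str:
    """KO-pair index as a two-column edge-list TSV."""
    lines = [f"{u}\t{d}" for (u, d) in sorted(kb.ko_pair_index)]
    return "\n".join(lines) + ("\n" if lines else "")
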