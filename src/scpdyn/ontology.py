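"""Leveled subcellular-process (SCP) ontology with horizontal interactions.

The ontology is a 1-4 level hierarchy of SCPs.  Each SCP is annotated with
gene symbols; SCPs of the same level may additionally be linked by weighted
*horizontal* interactions that quantify how strongly two processes cooperate
functionally.  A background gene list defines the statistical universe for
enrichment tests; annotations are always interpreted relative to it.

File dialects (all plain text, tab-delimited):

* hierarchy TSV with columns ``scp_id, parent_id, level, name`` (empty
  ``parent_id`` for level-1 roots; one row per parent link),
* annotations as GMT (``set_id<TAB>description<TAB>gene1<TAB>gene2...``),
* interactions TSV with columns ``scp_a, scp_b, strength``,
* background list with one gene symbol per line.

Gene symbols are upper-cased on ingestion so that mouse/rat/human casing
conventions compare equal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

VALID_LEVELS = (1, 2, 3, 4)


class OntologyError(ValueError):
    """Structural or format problem in ontology inputs."""


class ConfigurationError(ValueError):
    """Operation parameters inconsistent with the data."""


def _norm_gene(symbol: str) -> str:
    return symbol.strip().upper()


def normalize_genes(genes: Iterable[str]) -> frozenset[str]:
    """Upper-case and deduplicate gene symbols, dropping empty entries."""
    out = {_norm_gene(g) for g in genes}
    out.discard("")
    return frozenset(out)


@dataclass(frozen=True)
class SCP:
    """One subcellular process: an identifiable, leveled, gene-annotated unit."""

    scp_id: str
    name: str
    level: int
    genes: frozenset[str] = frozenset()
    parent_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.level not in VALID_LEVELS:
            raise OntologyError(f"SCP {self.scp_id!r}: level must be in {VALID_LEVELS}, got {self.level}")
        if self.level == 1 and self.parent_ids:
            raise OntologyError(f"level-1 SCP {self.scp_id!r} must not have parents")
        if any(not g for g in self.genes):
            raise OntologyError(f"SCP {self.scp_id!r}: empty gene symbol")


@dataclass(frozen=True)
class HorizontalInteraction:
    """Undirected same-level functional link between two SCPs."""

    scp_a: str
    scp_b: str
    strength: float

    def __post_init__(self) -> None:
        if self.scp_a == self.scp_b:
            raise OntologyError(f"self-interaction on {self.scp_a!r}")
        if not (self.strength >= 0 and math.isfinite(self.strength)):
            raise OntologyError(f"interaction {self.scp_a}-{self.scp_b}: strength must be finite and >= 0")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.scp_a, self.scp_b))


@dataclass(frozen=True)
class OntologyGraph:
    """Validated SCP hierarchy + horizontal interactions + background genes."""

    scps: Mapping[str, SCP]
    interactions: tuple[HorizontalInteraction, ...]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        seen_pairs: set[frozenset[str]] = set()
        for ia in self.interactions:
            for end in (ia.scp_a, ia.scp_b):
                if end not in self.scps:
                    raise OntologyError(f"interaction references unknown SCP {end!r}")
            if self.scps[ia.scp_a].level != self.scps[ia.scp_b].level:
                raise OntologyError(
                    f"interaction {ia.scp_a}-{ia.scp_b} crosses levels "
                    f"({self.scps[ia.scp_a].level} vs {self.scps[ia.scp_b].level})"
                )
            if ia.key in seen_pairs:
                raise OntologyError(f"duplicate interaction {ia.scp_a}-{ia.scp_b}")
            seen_pairs.add(ia.key)
        for scp in self.scps.values():
            for pid in scp.parent_ids:
                if pid not in self.scps:
                    raise OntologyError(f"SCP {scp.scp_id!r}: missing parent {pid!r}")
                if self.scps[pid].level != scp.level - 1:
                    raise OntologyError(
                        f"SCP {scp.scp_id!r} (level {scp.level}) has parent {pid!r} "
                        f"at level {self.scps[pid].level}, expected {scp.level - 1}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Parent links go strictly level -> level-1, so a cycle can only arise
        # from corrupted level fields; walk anyway for a hard guarantee.
        state: dict[str, int] = {}

        def visit(sid: str, stack: tuple[str, ...]) -> None:
            if state.get(sid) == 1:
                raise OntologyError(f"cyclic parent chain at {sid!r}: {' -> '.join(stack)}")
            if state.get(sid) == 2:
                return
            state[sid] = 1
            for pid in self.scps[sid].parent_ids:
                visit(pid, stack + (pid,))
            state[sid] = 2

        for sid in self.scps:
            visit(sid, (sid,))

    # -- convenience -----------------------------------------------------
    def scps_at_level(self, level: int) -> list[SCP]:
        return [s for s in self.scps.values() if s.level == level]

    def interactions_at_level(self, level: int) -> list[HorizontalInteraction]:
        return [ia for ia in self.interactions if self.scps[ia.scp_a].level == level]

    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for scp in self.scps.values():
            out |= scp.genes
        return frozenset(out)

    def genes_of(self, scp_ids: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for sid in scp_ids:
            out |= self.scps[sid].genes
        return frozenset(out)

    def interaction_strength(self, scp_a: str, scp_b: str) -> float | None:
        key = frozenset((scp_a, scp_b))
        for ia in self.interactions:
            if ia.key == key:
                return ia.strength
        return None


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def parse_gmt(source: str | Path) -> dict[str, frozenset[str]]:
    """Parse a GMT file into ``{set_id: genes}`` with duplicates collapsed."""
    sets: dict[str, frozenset[str]] = {}
    for line in Path(source).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise OntologyError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = normalize_genes(parts[2:])
    return sets


def load_ontology(
    hierarchy_source: str | Path,
    annotation_source: str | Path,
    interaction_source: str | Path,
    background_source: str | Path,
) -> OntologyGraph:
    """Load and validate an ontology from its four text files.

    Emits a per-level load report to the module logger.  Raises
    :class:`OntologyError` on missing parents, level-crossing interactions,
    or malformed rows.
    """
    hier = pd.read_csv(hierarchy_source, sep="\t", dtype={"scp_id": str, "parent_id": str})
    required = {"scp_id", "parent_id", "level", "name"}
    if missing := required - set(hier.columns):
        raise OntologyError(f"hierarchy file missing columns: {sorted(missing)}")

    annotations = parse_gmt(annotation_source)

    meta: dict[str, tuple[int, str]] = {}
    parents: dict[str, set[str]] = {}
    for row in hier.itertuples(index=False):
        sid = str(row.scp_id)
        level = int(row.level)
        if sid in meta and meta[sid] != (level, str(row.name)):
            raise OntologyError(f"conflicting level/name for SCP {sid!r}")
        meta[sid] = (level, str(row.name))
        pid = row.parent_id
        if pd.notna(pid) and str(pid).strip():
            parents.setdefault(sid, set()).add(str(pid).strip())

    scps = {
        sid: SCP(
            scp_id=sid,
            name=name,
            level=level,
            genes=annotations.get(sid, frozenset()),
            parent_ids=frozenset(parents.get(sid, set())),
        )
        for sid, (level, name) in meta.items()
    }

    inter = pd.read_csv(interaction_source, sep="\t", dtype={"scp_a": str, "scp_b": str})
    if missing := {"scp_a", "scp_b", "strength"} - set(inter.columns):
        raise OntologyError(f"interaction file missing columns: {sorted(missing)}")
    interactions = tuple(
        HorizontalInteraction(str(r.scp_a), str(r.scp_b), float(r.strength))
        for r in inter.itertuples(index=False)
    )

    background = normalize_genes(Path(background_source).read_text().splitlines())
    graph = OntologyGraph(scps=scps, interactions=interactions, background=background)

    counts = {lvl: sum(1 for s in scps.values() if s.level == lvl) for lvl in VALID_LEVELS}
    logger.info(
        "loaded ontology: %s SCPs (%s), %d interactions, %d background genes",
        len(scps),
        ", ".join(f"level {k}: {v}" for k, v in counts.items() if v),
        len(interactions),
        len(background),
    )
    return graph


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def apply_ortholog_map(ontology: OntologyGraph, mapping: Mapping[str, str]) -> OntologyGraph:
    """Replace annotated gene symbols via a two-column ortholog table.

    Symbols absent from ``mapping`` are kept unchanged; the background is
    mapped the same way.  This is a plain lookup — no database access.
    """
    table = {_norm_gene(k): _norm_gene(v) for k, v in mapping.items()}

    def remap(genes: frozenset[str]) -> frozenset[str]:
        return frozenset(table.get(g, g) for g in genes)

    scps = {sid: replace(s, genes=remap(s.genes)) for sid, s in ontology.scps.items()}
    return OntologyGraph(scps=scps, interactions=ontology.interactions, background=remap(ontology.background))


def restrict_to_background(ontology: OntologyGraph, measurable_genes: Iterable[str]) -> OntologyGraph:
    """Keep only genes that had a chance of being measured.

    Annotations are intersected with ``measurable ∩ background`` and the
    background itself shrinks to ``background ∩ measurable``.  SCPs are never
    deleted, only depleted.
    """
    measurable = normalize_genes(measurable_genes)
    if not measurable:
        raise ConfigurationError("measurable gene set is empty")
    new_background = ontology.background & measurable
    if not new_background:
        raise ConfigurationError("no measurable gene is part of the background")
    scps = {
        sid: replace(scp, genes=scp.genes & new_background)
        for sid, scp in ontology.scps.items()
    }
    return OntologyGraph(scps=scps, interactions=ontology.interactions, background=new_background)


def create_composite_scp(
    ontology: OntologyGraph,
    new_name: str,
    level: int,
    member_scp_ids: list[str],
    new_id: str | None = None,
) -> OntologyGraph:
    """Add a composite SCP whose genes are the union of the members' genes.

    Mirrors the construction of an umbrella process (e.g. gathering all
    mitochondria-related SCPs scattered across branches under one new
    level-1 parent).  Members one level below the composite are re-parented
    to it; members at other levels keep their parents.  Original SCPs are
    retained unchanged otherwise.
    """
    if not member_scp_ids:
        raise OntologyError("composite SCP needs at least one member")
    for mid in member_scp_ids:
        if mid not in ontology.scps:
            raise OntologyError(f"composite member {mid!r} not in ontology")
    new_id = new_id or new_name
    if new_id in ontology.scps:
        raise OntologyError(f"SCP id {new_id!r} already exists")
    if any(s.name == new_name for s in ontology.scps.values()):
        raise OntologyError(f"SCP name {new_name!r} already exists")

    genes = ontology.genes_of(member_scp_ids)
    composite = SCP(scp_id=new_id, name=new_name, level=level, genes=genes)

    scps = dict(ontology.scps)
    scps[new_id] = composite
    for mid in member_scp_ids:
        member = scps[mid]
        if member.level == level + 1:
            scps[mid] = replace(member, parent_ids=member.parent_ids | {new_id})
    return OntologyGraph(scps=scps, interactions=ontology.interactions, background=ontology.background)


def interaction_strength_cutoff(
    ontology: OntologyGraph,
    level: int,
    top_fraction: float,
    exclude_scp_ids: Iterable[str] = (),
) -> float:
    """Strength threshold selecting the top ``top_fraction`` of a level's interactions.

    Interactions with strength >= the returned value constitute the top set;
    ties at the threshold are included.  ``exclude_scp_ids`` drops
    interactions touching listed SCPs (used to keep composite SCPs out of
    the percentile computation).
    """
    if not (0 < top_fraction <= 1):
        raise ConfigurationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    excluded = set(exclude_scp_ids)
    strengths = sorted(
        (
            ia.strength
            for ia in ontology.interactions_at_level(level)
            if ia.scp_a not in excluded and ia.scp_b not in excluded
        ),
        reverse=True,
    )
    if not strengths:
        raise ConfigurationError(f"no horizontal interactions at level {level}")
    k = math.ceil(top_fraction * len(strengths))
    return strengths[k - 1]
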