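"""Standard and dynamic SCP enrichment analysis.

Standard enrichment asks, per SCP and per (time point, direction) gene
list, whether list genes are over-represented among the SCP's annotated
genes relative to the background (one-sided Fisher's exact test).

Dynamic enrichment additionally tests *function-specific* SCPs: unions of
two or three same-level SCPs that are strongly connected by horizontal
interactions (top 20% of level-2 interactions, top 25% of level-3 by
default).  Single seed SCPs and generated combinations compete in one
ranking; the top predictions (3 for level 2, 5 for level 3) define a
context-specific SCP network in which member SCPs of the same prediction
are connected.

No multiple-testing correction is applied to enrichment p-values; results
are reported at nominal significance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .ontology import ConfigurationError, OntologyGraph, interaction_strength_cutoff

Direction = Literal["up", "down"]

DEFAULT_TOP_FRACTION = {2: 0.20, 3: 0.25}
DEFAULT_TOP_K = {2: 3, 3: 5}


@dataclass(frozen=True)
class FunctionSpecificSCP:
    """Union of 2-3 same-level SCPs connected by strong horizontal interactions."""

    member_ids: tuple[str, ...]
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.member_ids) not in (2, 3):
            raise ValueError("function-specific SCP must have 2 or 3 members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("function-specific SCP members must be distinct")

    @property
    def unit_id(self) -> str:
        return "+".join(sorted(self.member_ids))


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher outcome for one unit (single SCP or combination) on one gene list."""

    unit_id: str
    member_ids: tuple[str, ...]
    overlap: int
    unit_size: int
    list_size: int
    background_size: int
    p_value: float
    direction: Direction | None = None
    time_point: float | None = None
    significant: bool | None = None

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)


def fisher_scp_test(
    gene_list: Iterable[str],
    unit_genes: Iterable[str],
    background: Iterable[str],
) -> tuple[float, int]:
    """One-sided over-representation Fisher p for a gene list against a unit.

    Returns ``(p_value, overlap)``.  The 2x2 table is (overlap, list-only,
    unit-only, neither) over the background universe; the p-value is the
    hypergeometric upper tail P(X >= overlap).
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("background is empty")
    gl = frozenset(gene_list) & bg
    ug = frozenset(unit_genes) & bg
    overlap = len(gl & ug)
    table = [
        [overlap, len(gl) - overlap],
        [len(ug) - overlap, len(bg) - len(gl) - len(ug) + overlap],
    ]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return min(p, 1.0), overlap


def _result_for_unit(
    unit_id: str,
    member_ids: tuple[str, ...],
    unit_genes: frozenset[str],
    gene_list: frozenset[str],
    background: frozenset[str],
    **annotations,
) -> EnrichmentResult:
    p, overlap = fisher_scp_test(gene_list, unit_genes, background)
    return EnrichmentResult(
        unit_id=unit_id,
        member_ids=member_ids,
        overlap=overlap,
        unit_size=len(unit_genes & background),
        list_size=len(gene_list & background),
        background_size=len(background),
        p_value=p,
        **annotations,
    )


def standard_enrichment(
    calls_by_stratum: Mapping[tuple[float, Direction], Iterable[str]],
    ontology: OntologyGraph,
    alpha: float = 0.05,
    levels: Sequence[int] = (1, 2, 3, 4),
) -> list[EnrichmentResult]:
    """Fisher test every SCP against every (time point, direction) gene list.

    All results are retained (for timelines); those with nominal
    p <= ``alpha`` carry ``significant=True``.  Empty strata are skipped.
    """
    results: list[EnrichmentResult] = []
    for (time_point, direction) in sorted(calls_by_stratum):
        gene_list = frozenset(g.upper() for g in calls_by_stratum[(time_point, direction)])
        gene_list &= ontology.background
        if not gene_list:
            continue
        for level in levels:
            for scp in sorted(ontology.scps_at_level(level), key=lambda s: s.scp_id):
                res = _result_for_unit(
                    scp.scp_id,
                    (scp.scp_id,),
                    scp.genes,
                    gene_list,
                    ontology.background,
                    direction=direction,
                    time_point=time_point,
                )
                results.append(replace(res, significant=res.p_value <= alpha))
    return results


def generate_combinations(
    seed_scps: Iterable[str],
    ontology: OntologyGraph,
    top_fraction: float | None = None,
    require_all_pairs: bool = False,
) -> list[FunctionSpecificSCP]:
    """Combine strongly connected seed SCPs into function-specific units.

    Pairs require an above-cutoff interaction; triples require the three
    members to form a connected subgraph under above-cutoff edges (or a
    full clique with ``require_all_pairs``).  The cutoff is the level-wide
    top-``top_fraction`` interaction-strength threshold.
    """
    seeds = sorted(set(seed_scps))
    if not seeds:
        return []
    levels = {ontology.scps[s].level for s in seeds}
    if len(levels) > 1:
        raise ConfigurationError(f"seed SCPs span levels {sorted(levels)}")
    level = levels.pop()
    if top_fraction is None:
        top_fraction = DEFAULT_TOP_FRACTION.get(level, 0.25)
    try:
        cutoff = interaction_strength_cutoff(ontology, level, top_fraction)
    except ConfigurationError:
        return []

    strong = nx.Graph()
    strong.add_nodes_from(seeds)
    for a, b in itertools.combinations(seeds, 2):
        strength = ontology.interaction_strength(a, b)
        if strength is not None and strength >= cutoff:
            strong.add_edge(a, b)

    combos: list[FunctionSpecificSCP] = []
    for a, b in itertools.combinations(seeds, 2):
        if strong.has_edge(a, b):
            combos.append(FunctionSpecificSCP((a, b), ontology.genes_of((a, b))))
    for trio in itertools.combinations(seeds, 3):
        n_edges = sum(strong.has_edge(x, y) for x, y in itertools.combinations(trio, 2))
        connected = n_edges == 3 if require_all_pairs else (
            n_edges >= 2 and nx.is_connected(strong.subgraph(trio))
        )
        if connected:
            combos.append(FunctionSpecificSCP(trio, ontology.genes_of(trio)))
    return combos


def _rank_key(res: EnrichmentResult) -> tuple:
    # smaller p, then fewer members, then larger overlap, then id
    return (res.p_value, len(res.member_ids), -res.overlap, res.unit_id)


def dynamic_enrichment(
    gene_list: Iterable[str],
    ontology: OntologyGraph,
    level: int,
    top_fraction: float | None = None,
    top_k: int | None = None,
    include_singles: bool = True,
    require_all_pairs: bool = False,
    direction: Direction | None = None,
    time_point: float | None = None,
) -> list[EnrichmentResult]:
    """Rank single SCPs and their function-specific combinations by Fisher p.

    Seeds are the level's SCPs containing at least one list gene; candidate
    units are the seeds (unless ``include_singles`` is off) plus all
    combinations generated from them.  Returns the ``top_k`` predictions
    (default 3 for level 2, 5 for level 3) in rank order; ties break toward
    fewer member SCPs, then larger overlap, then lexicographic id.
    """
    genes = frozenset(g.upper() for g in gene_list) & ontology.background
    if top_k is None:
        top_k = DEFAULT_TOP_K.get(level, 3)
    seeds = [s.scp_id for s in ontology.scps_at_level(level) if s.genes & genes]
    if not seeds:
        return []

    candidates: list[tuple[str, tuple[str, ...], frozenset[str]]] = []
    if include_singles:
        for sid in sorted(seeds):
            candidates.append((sid, (sid,), ontology.scps[sid].genes))
    for combo in generate_combinations(seeds, ontology, top_fraction, require_all_pairs):
        candidates.append((combo.unit_id, combo.member_ids, combo.genes))

    results = [
        _result_for_unit(uid, members, ugenes, genes, ontology.background,
                         direction=direction, time_point=time_point)
        for uid, members, ugenes in candidates
    ]
    results.sort(key=_rank_key)
    return results[:top_k]


def build_scp_network(
    predictions_by_stratum: Mapping[tuple[float, Direction], Sequence[EnrichmentResult]],
) -> nx.Graph:
    """Assemble the context-specific SCP network from top predictions.

    Nodes are the member SCPs of every retained prediction, annotated with
    the (time, direction) strata in which they appear.  Members of the same
    multi-SCP prediction are connected pairwise (clique over members); each
    edge records the prediction that certifies it.
    """
    net = nx.Graph()
    for (time_point, direction), predictions in sorted(predictions_by_stratum.items()):
        for res in predictions:
            for sid in res.member_ids:
                if not net.has_node(sid):
                    net.add_node(sid, strata=[])
                net.nodes[sid]["strata"].append((time_point, direction))
            for a, b in itertools.combinations(sorted(res.member_ids), 2):
                if not net.has_edge(a, b):
                    net.add_edge(a, b, predictions=[])
                net.edges[a, b]["predictions"].append(
                    (res.unit_id, time_point, direction)
                )
    return net


def assemble_timelines(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Per-SCP timelines of -log10 p for up and down gene lists.

    Returns a long-format frame (scp_id, direction, time_point,
    neg_log10_p) covering the full time grid; an SCP untested in a stratum
    appears with NaN, not zero.  The significance line -log10(0.05) is
    stored in ``frame.attrs['significance_line']``.
    """
    rows = [
        {
            "scp_id": r.unit_id,
            "direction": r.direction,
            "time_point": r.time_point,
            "neg_log10_p": r.neg_log10_p,
        }
        for r in results
        if len(r.member_ids) == 1 and r.time_point is not None
    ]
    frame = pd.DataFrame(rows, columns=["scp_id", "direction", "time_point", "neg_log10_p"])
    if not frame.empty:
        times = sorted(frame["time_point"].unique())
        full = pd.MultiIndex.from_product(
            [sorted(frame["scp_id"].unique()), ["up", "down"], times],
            names=["scp_id", "direction", "time_point"],
        )
        frame = (
            frame.set_index(["scp_id", "direction", "time_point"])
            .reindex(full)
            .reset_index()
        )
    frame.attrs["significance_line"] = -math.log10(0.05)
    return frame


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def predictions_to_frame(
    predictions_by_stratum: Mapping[tuple[float, Direction], Sequence[EnrichmentResult]],
) -> pd.DataFrame:
    rows = []
    for (time_point, direction), preds in sorted(predictions_by_stratum.items()):
        for rank, res in enumerate(preds, start=1):
            rows.append(
                {
                    "time_point": time_point,
                    "direction": direction,
                    "rank": rank,
                    "unit_id": res.unit_id,
                    "n_members": len(res.member_ids),
                    "overlap": res.overlap,
                    "unit_size": res.unit_size,
                    "list_size": res.list_size,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


def network_to_frames(net: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (source, target, time, direction, prediction_id) + node table."""
    edges = []
    for a, b, data in net.edges(data=True):
        for unit_id, time_point, direction in data["predictions"]:
            edges.append(
                {"source": a, "target": b, "time_point": time_point,
                 "direction": direction, "prediction_id": unit_id}
            )
    nodes = [
        {"scp_id": n, "strata": ";".join(f"{t}:{d}" for t, d in data["strata"])}
        for n, data in net.nodes(data=True)
    ]
    return pd.DataFrame(edges), pd.DataFrame(nodes)
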