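"""Seedable synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the real inputs — a leveled SCP
ontology with horizontal interactions, treated/control FPKM tables over
four time points, two-run iTRAQ-style protein tables with per-run
untreated references, and chamber fluorescence profiles with exponential
outgrowth decay — while planting controllable signals (enriched SCPs,
shifted proteins, knockdown effects, damaged cell bodies).  Each
generator is deterministic under a fixed seed and returns a ground-truth
manifest sufficient to score the consuming stage without inspecting
generator internals.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .nog import IntensityProfile, resample_profile
from .ontology import SCP, HorizontalInteraction, OntologyGraph
from .vesicle import ModelParameters, analytic_parameter_solution

Regime = Literal["feasible", "near_stall", "stalled"]


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OntologySpec:
    """Shape of the synthetic SCP ontology."""

    scps_per_level: tuple[int, int, int, int] = (5, 10, 20, 40)
    genes_per_scp: int = 15
    background_size: int = 2000
    interaction_density: float = 0.5      # fraction of same-level pairs linked
    strong_pair_fraction: float = 0.2     # fraction of links designated strong

    def __post_init__(self) -> None:
        if self.genes_per_scp > self.background_size:
            raise ValueError("more genes per SCP than background genes")
        if not (0 < self.interaction_density <= 1):
            raise ValueError("interaction_density must be in (0, 1]")
        if not (0 < self.strong_pair_fraction <= 1):
            raise ValueError("strong_pair_fraction must be in (0, 1]")


def synth_ontology(
    spec: OntologySpec = OntologySpec(), seed: int = 0
) -> tuple[OntologyGraph, dict]:
    """Build a leveled ontology with overlapping annotations and strong pairs.

    Levels 2-4 draw ``genes_per_scp`` genes each from the background (with
    overlap across SCPs); level-1 SCPs aggregate their children's genes.
    Horizontal interactions receive strengths in (0, 1); the designated
    strong pairs carry exactly the top ``strong_pair_fraction`` of each
    level's strengths and are recorded in the ground truth.
    """
    rng = np.random.default_rng(seed)
    background = [f"G{i:05d}" for i in range(spec.background_size)]

    scps: dict[str, SCP] = {}
    ids_by_level: dict[int, list[str]] = {}
    for level, count in zip((1, 2, 3, 4), spec.scps_per_level):
        ids = [f"L{level}_{i:03d}" for i in range(count)]
        ids_by_level[level] = ids
        for sid in ids:
            parents = frozenset()
            if level > 1:
                parents = frozenset({str(rng.choice(ids_by_level[level - 1]))})
            genes = frozenset()
            if level > 1:
                genes = frozenset(rng.choice(background, spec.genes_per_scp, replace=False))
            scps[sid] = SCP(sid, f"synthetic process {sid}", level, genes, parents)

    # level-1 containers aggregate their children's genes
    for sid in ids_by_level[1]:
        child_genes: set[str] = set()
        for child in scps.values():
            if sid in child.parent_ids:
                child_genes |= child.genes
        scps[sid] = SCP(sid, scps[sid].name, 1, frozenset(child_genes))

    interactions: list[HorizontalInteraction] = []
    strong_pairs: dict[int, list[tuple[str, str]]] = {}
    for level in (2, 3, 4):
        ids = ids_by_level[level]
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
        n_links = max(1, int(round(spec.interaction_density * len(pairs))))
        chosen = [pairs[i] for i in rng.choice(len(pairs), n_links, replace=False)]
        strengths = np.sort(rng.uniform(0.0, 1.0, n_links))[::-1]
        n_strong = max(1, math.ceil(spec.strong_pair_fraction * n_links))
        order = rng.permutation(n_links)
        strong_idx = order[:n_strong]
        strong_pairs[level] = sorted(chosen[i] for i in strong_idx)
        rank = np.empty(n_links, dtype=int)
        rank[order] = np.arange(n_links)  # strong pairs get the largest strengths
        for (a, b), r in zip(chosen, rank):
            interactions.append(HorizontalInteraction(a, b, float(strengths[r])))

    graph = OntologyGraph(
        scps=scps, interactions=tuple(interactions), background=frozenset(background)
    )
    truth = {
        "strong_pairs": strong_pairs,
        "ids_by_level": ids_by_level,
        "seed": seed,
    }
    return graph, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSpec:
    """Treated/control FPKM-like design over four sampling times.

    ``planted`` maps (time point, direction) to the SCP ids whose genes
    shift; ``planted_gene_fraction`` controls how many of each planted
    SCP's genes respond.  A configurable fraction of responding genes
    shifts only to an intermediate fold change between the relaxed and
    stringent cutoffs, exercising the dual-cutoff calling design.
    """

    time_points: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    planted: Mapping[tuple[float, str], tuple[str, ...]] = field(default_factory=dict)
    planted_gene_fraction: float = 1.0
    effect_log2fc: float = math.log2(1.6)
    intermediate_fraction: float = 0.0    # shifted only to within [log2 1.3, log2 1.5)
    abundance_log_mean: float = math.log(50.0)
    abundance_log_sd: float = 1.0
    noise_sigma: float = 0.02             # multiplicative measurement noise (log scale)
    planted_p_max: float = 1e-5
    seed_offset: int = 0


def synth_expression(
    ontology: OntologyGraph,
    spec: ExpressionSpec = ExpressionSpec(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an expression table (gene, time_h, fpkm_treated, fpkm_control, p_raw, p_adj).

    Null genes have equal expected abundance in both arms and uniform raw
    p-values; planted genes shift multiplicatively at their designated
    times/directions and receive near-zero p-values.  Adjusted p-values
    are Benjamini-Hochberg within each time point.
    """
    from .diffexpr import bh_adjust

    if spec.effect_log2fc == 0 and spec.planted:
        import warnings

        warnings.warn("planted SCPs with zero effect size produce no signal")
    for (_, direction), scp_ids in spec.planted.items():
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {direction!r}")
        for sid in scp_ids:
            if sid not in ontology.scps:
                raise ValueError(f"planted SCP {sid!r} not in ontology")

    rng = np.random.default_rng(seed + spec.seed_offset)
    genes = sorted(ontology.background)
    n = len(genes)
    base = rng.lognormal(spec.abundance_log_mean, spec.abundance_log_sd, n)

    planted_genes: dict[tuple[float, str], dict[str, float]] = {}
    truth_strong: dict[str, set[str]] = {}
    truth_intermediate: dict[str, set[str]] = {}
    for key, scp_ids in spec.planted.items():
        chosen: dict[str, float] = {}
        for sid in scp_ids:
            members = sorted(ontology.scps[sid].genes)
            k = max(1, int(round(spec.planted_gene_fraction * len(members))))
            picked = [members[i] for i in rng.choice(len(members), k, replace=False)]
            for g in picked:
                if rng.uniform() < spec.intermediate_fraction:
                    lfc = rng.uniform(math.log2(1.3), math.log2(1.5) - 1e-9)
                    truth_intermediate.setdefault(f"{key[0]}:{key[1]}", set()).add(g)
                else:
                    lfc = spec.effect_log2fc
                    truth_strong.setdefault(f"{key[0]}:{key[1]}", set()).add(g)
                chosen[g] = lfc
        planted_genes[key] = chosen

    gene_index = {g: i for i, g in enumerate(genes)}
    chunks = []
    for t in spec.time_points:
        lfc = np.zeros(n)
        for g, x in planted_genes.get((t, "up"), {}).items():
            lfc[gene_index[g]] += x
        for g, x in planted_genes.get((t, "down"), {}).items():
            lfc[gene_index[g]] -= x
        noise_t = rng.lognormal(0.0, spec.noise_sigma, n)
        noise_c = rng.lognormal(0.0, spec.noise_sigma, n)
        p_raw = rng.uniform(0.0, 1.0, n)
        p_raw = np.where(lfc != 0.0, p_raw * spec.planted_p_max, p_raw)
        chunks.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "time_h": t,
                    "fpkm_treated": base * (2.0 ** lfc) * noise_t,
                    "fpkm_control": base * noise_c,
                    "p_raw": p_raw,
                }
            )
        )
    frame = pd.concat(chunks, ignore_index=True)
    frame["p_adj"] = np.concatenate(
        [bh_adjust(sub["p_raw"].to_numpy()) for _, sub in frame.groupby("time_h", sort=True)]
    )
    truth = {
        "planted_strong": {k: sorted(v) for k, v in truth_strong.items()},
        "planted_intermediate": {k: sorted(v) for k, v in truth_intermediate.items()},
        "planted_scps": {f"{t}:{d}": list(v) for (t, d), v in spec.planted.items()},
        "seed": seed,
    }
    return frame, truth


def expression_records(frame: pd.DataFrame):
    """Convert a synthetic expression frame into ExpressionRecord objects."""
    from .diffexpr import ExpressionRecord

    return [
        ExpressionRecord(
            gene=str(r.gene),
            time_point=float(r.time_h),
            abundance_treated=float(r.fpkm_treated),
            abundance_control=float(r.fpkm_control),
            adjusted_p=float(r.p_adj),
        )
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomicsSpec:
    """Two-run iTRAQ-style design with per-run untreated references.

    Run 1 carries the treated replicates, run 2 the vehicle replicates;
    both contain two aliquots of the same untreated samples, which anchor
    the within-run normalization.  Run-level multiplicative batch factors
    emulate labeling/loading differences between runs.
    """

    n_proteins: int = 300
    n_planted: int = 20
    planted_shift_log2: float = math.log2(1.2)
    replicates_per_group: int = 2
    single_peptide_fraction: float = 0.15
    noise_sigma: float = 0.01             # replicate noise, natural-log scale
    batch_factors: tuple[float, float] = (1.0, 3.0)
    abundance_log_mean: float = math.log(1000.0)
    abundance_log_sd: float = 1.0


def synth_proteomics(
    spec: ProteomicsSpec = ProteomicsSpec(), seed: int = 0
) -> tuple[list, dict]:
    """Simulate raw (un-normalized) protein records plus ground truth.

    Planted proteins shift by ``planted_shift_log2`` in the treated arm; a
    configurable fraction of proteins is identified by a single peptide
    (and must be discarded by the two-peptide rule even when shifted).
    """
    from .diffexpr import ProteinRecord

    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    base = rng.lognormal(spec.abundance_log_mean, spec.abundance_log_sd, spec.n_proteins)
    peptide_counts = np.where(
        rng.uniform(size=spec.n_proteins) < spec.single_peptide_fraction,
        1,
        rng.integers(2, 16, spec.n_proteins),
    )
    planted_idx = rng.choice(spec.n_proteins, spec.n_planted, replace=False)
    planted = {proteins[i] for i in planted_idx}
    directions = {proteins[i]: (1 if rng.uniform() < 0.5 else -1) for i in planted_idx}

    nrep = spec.replicates_per_group
    records = []
    for run_index, run_id in enumerate(("run1", "run2")):
        batch = spec.batch_factors[run_index]
        group_role = "treated" if run_index == 0 else "vehicle"
        for i, prot in enumerate(proteins):
            values: dict[str, float] = {}
            roles: dict[str, str] = {}
            for j in range(2):
                label = f"{run_id}_untreated_{j}"
                values[label] = float(base[i] * batch * rng.lognormal(0.0, spec.noise_sigma))
                roles[label] = "untreated"
            shift = 0.0
            if prot in planted and group_role == "treated":
                shift = directions[prot] * spec.planted_shift_log2
            for j in range(nrep):
                label = f"{run_id}_{group_role}_{j}"
                values[label] = float(
                    base[i] * batch * (2.0 ** shift) * rng.lognormal(0.0, spec.noise_sigma)
                )
                roles[label] = group_role
            records.append(
                ProteinRecord(
                    protein_id=prot,
                    peptide_count=int(peptide_counts[i]),
                    run_id=run_id,
                    sample_values=values,
                    sample_roles=roles,
                )
            )
    truth = {
        "planted": sorted(planted),
        "directions": {p: ("up" if d > 0 else "down") for p, d in directions.items()},
        "detectable": sorted(p for p in planted if peptide_counts[proteins.index(p)] >= 2),
        "batch_factors": dict(zip(("run1", "run2"), spec.batch_factors)),
        "seed": seed,
    }
    return records, truth


# ---------------------------------------------------------------------------
# fluorescence profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSpec:
    """Chamber fluorescence profiles: exponential outgrowth decay + noise.

    Neurite-side control profiles follow amplitude * exp(-(d - 100)/lambda)
    so that the noise-free control equals its amplitude at the 100 μm
    normalization anchor; knockdown profiles are scaled by per-gene effect
    multipliers (< 1 inhibits outgrowth).  Cell-body profiles carry a
    tubulin ridge near the wall, which the damage flag displaces beyond
    the 50 μm search window.
    """

    decay_lambda: float = 200.0           # μm
    max_distance: float = 600.0           # μm profile coverage
    amplitude: float = 100.0              # intensity at the 100 μm anchor
    noise_sd: float = 5.0                 # additive Gaussian, intensity units
    noise_correlation_um: float = 150.0   # spatial correlation scale of the noise
    n_experiments: int = 1
    controls_per_experiment: int = 2
    replicates_per_gene: int = 4
    effect_multipliers: Mapping[str, float] = field(default_factory=dict)
    experiment_scale_sd: float = 0.2      # lognormal inter-experiment amplitude spread
    raw_step: float = 0.5                 # μm spacing of simulated raw measurements


def _smooth_noise(rng: np.random.Generator, d: np.ndarray, sd: float, corr: float) -> np.ndarray:
    """Spatially smooth Gaussian field: iid knots every ``corr`` μm, interpolated.

    Chamber profiles are pixel-row averages, so their noise varies slowly
    with distance (staining density, illumination) rather than per point.
    """
    if sd == 0:
        return np.zeros_like(d)
    knots = np.arange(d[0], d[-1] + corr, corr)
    return np.interp(d, knots, rng.normal(0.0, sd, knots.size))


def _decay_profile(
    rng: np.random.Generator,
    spec: ProfileSpec,
    amplitude: float,
    multiplier: float,
    **meta,
) -> IntensityProfile:
    d = np.arange(0.0, spec.max_distance + spec.raw_step / 2, spec.raw_step)
    clean = amplitude * multiplier * np.exp(-(d - 100.0) / spec.decay_lambda)
    noise = _smooth_noise(rng, d, spec.noise_sd, spec.noise_correlation_um)
    noisy = np.clip(clean + noise, 0.0, None)
    return resample_profile(list(zip(d, noisy)), side="neurite", **meta)


def synth_profiles(
    spec: ProfileSpec = ProfileSpec(), seed: int = 0
) -> tuple[list[IntensityProfile], pd.DataFrame, dict]:
    """Neurite-side control and knockdown profiles with a manifest.

    Returns (profiles, manifest, truth); the manifest lists chamber, side,
    condition and experiment per profile in the same order.
    """
    rng = np.random.default_rng(seed)
    profiles: list[IntensityProfile] = []
    rows = []
    for e in range(spec.n_experiments):
        exp_id = f"exp{e}"
        scale = float(rng.lognormal(0.0, spec.experiment_scale_sd))
        amplitude = spec.amplitude * scale
        for c in range(spec.controls_per_experiment):
            chamber = f"{exp_id}_ctrl{c}"
            profiles.append(
                _decay_profile(rng, spec, amplitude, 1.0, chamber_id=chamber,
                               experiment_id=exp_id, condition="control")
            )
            rows.append({"chamber": chamber, "experiment": exp_id,
                         "condition": "control", "side": "neurite"})
        for gene, mult in spec.effect_multipliers.items():
            for r in range(spec.replicates_per_gene):
                chamber = f"{exp_id}_{gene}_{r}"
                profiles.append(
                    _decay_profile(rng, spec, amplitude, mult, chamber_id=chamber,
                                   experiment_id=exp_id, condition=gene)
                )
                rows.append({"chamber": chamber, "experiment": exp_id,
                             "condition": gene, "side": "neurite"})
    truth = {
        "effect_multipliers": dict(spec.effect_multipliers),
        "decay_lambda": spec.decay_lambda,
        "seed": seed,
    }
    return profiles, pd.DataFrame(rows), truth


def synth_cell_body_profile(
    damaged: bool = False,
    seed: int = 0,
    mode: Literal["displaced", "attenuated"] = "displaced",
    noise_sd: float = 0.0,
    **meta,
) -> IntensityProfile:
    """Cell-body profile with an intact or damage-mimicking tubulin ridge.

    Undamaged: a strong ridge at 10 μm dominating the first 100 μm.
    ``displaced`` damage moves the ridge to 70 μm (outside the 50 μm
    search window); ``attenuated`` keeps it at 10 μm but below 85% of the
    window maximum (a brighter far ridge sits at 90 μm).
    """
    rng = np.random.default_rng(seed)
    d = np.arange(0.0, 120.0 + 0.25, 0.5)
    background = 15.0 + 0.02 * d
    if not damaged:
        ridge = 100.0 * np.exp(-((d - 10.0) ** 2) / (2 * 4.0 ** 2))
        far = np.zeros_like(d)
    elif mode == "displaced":
        ridge = 100.0 * np.exp(-((d - 70.0) ** 2) / (2 * 4.0 ** 2))
        far = np.zeros_like(d)
    else:
        ridge = 55.0 * np.exp(-((d - 10.0) ** 2) / (2 * 4.0 ** 2))
        far = 100.0 * np.exp(-((d - 90.0) ** 2) / (2 * 4.0 ** 2))
    v = np.clip(background + ridge + far + rng.normal(0.0, noise_sd, d.size), 0.0, None)
    meta.setdefault("side", "cell_body")
    return resample_profile(list(zip(d, v)), **meta)


# ---------------------------------------------------------------------------
# model parameters
# ---------------------------------------------------------------------------

def default_model_params(regime: Regime = "feasible", seed: int = 0) -> ModelParameters:
    """Parameter set whose analytic solution lies in the requested regime.

    ``feasible`` sits well above both back-transport thresholds,
    ``near_stall`` just above the stall bound (required totals at least
    twice the large-back-rate asymptote), ``stalled`` below it.  The
    construction is verified against the analytic solution before return.
    """
    rng = np.random.default_rng(seed)
    jitter = lambda: float(rng.uniform(0.95, 1.05))
    base = ModelParameters(
        kinesin_speed=3600.0 * jitter(),
        dynein_speed=2880.0 * jitter(),
        growth_cone_rest_area=50.0 * jitter(),
    )
    demand = base.shaft_area_per_length * base.target_velocity
    q_cap = max(
        base.snares_per_anterograde_vesicle * demand
        / (base.snare_cap - base.snares_per_anterograde_vesicle),
        base.receptors_per_anterograde_vesicle * demand
        / (base.kinesin_receptor_cap - base.receptors_per_anterograde_vesicle),
    )
    back = {"feasible": 3.0 * q_cap, "near_stall": 1.02 * q_cap, "stalled": 0.8 * q_cap}[regime]
    probe = analytic_parameter_solution(base.target_velocity, max(back, 1.02 * q_cap), base)
    params = replace_params(
        base,
        back_transport_rate=back,
        snare_synthesis_rate=probe.required_snare_synthesis,
        receptor_synthesis_rate=probe.required_receptor_synthesis,
    )
    sol = analytic_parameter_solution(params.target_velocity, back, params)
    if regime == "stalled":
        if sol.feasible:
            raise RuntimeError("stalled regime construction produced a feasible solution")
        return params
    if not sol.feasible:
        raise RuntimeError(f"{regime} regime construction infeasible: {sol.detail}")
    if regime == "near_stall":
        asym = analytic_parameter_solution(params.target_velocity, 10.0 * q_cap, params)
        if sol.required_snare_total < 2.0 * asym.required_snare_total:
            raise RuntimeError("near_stall regime not past the rapid-increase threshold")
    return params


def replace_params(params: ModelParameters, **changes) -> ModelParameters:
    from dataclasses import replace

    return replace(params, **changes)


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------

def write_scenario(out_dir: str | Path, seed: int = 0) -> dict[str, str]:
    """Write a complete end-to-end fixture in the file dialects the pipeline reads.

    Emits ontology (hierarchy TSV, annotations GMT, interactions TSV,
    background list), an expression TSV, a proteomics TSV, profile CSVs
    with a manifest, model parameters YAML, and a ground-truth JSON.
    Returns the mapping of artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    ontology, onto_truth = synth_ontology(seed=seed)
    hier_rows, gmt_lines = [], []
    for scp in ontology.scps.values():
        parents = sorted(scp.parent_ids) or [""]
        for pid in parents:
            hier_rows.append({"scp_id": scp.scp_id, "parent_id": pid,
                              "level": scp.level, "name": scp.name})
        gmt_lines.append("\t".join([scp.scp_id, scp.name, *sorted(scp.genes)]))
    pd.DataFrame(hier_rows).to_csv(out / "hierarchy.tsv", sep="\t", index=False)
    (out / "annotations.gmt").write_text("\n".join(gmt_lines) + "\n")
    pd.DataFrame(
        [{"scp_a": ia.scp_a, "scp_b": ia.scp_b, "strength": ia.strength}
         for ia in ontology.interactions]
    ).to_csv(out / "interactions.tsv", sep="\t", index=False)
    (out / "background.txt").write_text("\n".join(sorted(ontology.background)) + "\n")
    paths.update(hierarchy=str(out / "hierarchy.tsv"), annotations=str(out / "annotations.gmt"),
                 interactions=str(out / "interactions.tsv"), background=str(out / "background.txt"))

    strong_pair = onto_truth["strong_pairs"][2][0]
    expr_spec = ExpressionSpec(
        planted={(6.0, "up"): tuple(strong_pair)}, planted_gene_fraction=0.4
    )
    frame, expr_truth = synth_expression(ontology, expr_spec, seed=seed)
    frame.to_csv(out / "expression.tsv", sep="\t", index=False)
    paths["expression"] = str(out / "expression.tsv")

    records, prot_truth = synth_proteomics(seed=seed)
    prot_rows = [
        {"protein": r.protein_id, "peptides": r.peptide_count, "run": r.run_id,
         "sample": label, "role": r.sample_roles[label], "value": value}
        for r in records
        for label, value in r.sample_values.items()
    ]
    pd.DataFrame(prot_rows).to_csv(out / "proteomics.tsv", sep="\t", index=False)
    paths["proteomics"] = str(out / "proteomics.tsv")

    spec = ProfileSpec(effect_multipliers={"GENEA": 0.5, "GENEB": 1.0})
    profiles, manifest, prof_truth = synth_profiles(spec, seed=seed)
    profile_dir = out / "profiles"
    profile_dir.mkdir(exist_ok=True)
    files = []
    for prof, row in zip(profiles, manifest.to_dict("records")):
        fname = f"{row['chamber']}.csv"
        pd.DataFrame({"distance_um": prof.distances, "mean_gray": prof.intensities}).to_csv(
            profile_dir / fname, index=False
        )
        files.append({**row, "file": f"profiles/{fname}", "gene": row["condition"], "offset": 0.0})
    pd.DataFrame(files).to_csv(out / "profile_manifest.tsv", sep="\t", index=False)
    paths["profile_manifest"] = str(out / "profile_manifest.tsv")

    default_model_params("feasible", seed=seed).to_yaml(out / "model_params.yaml")
    paths["model_params"] = str(out / "model_params.yaml")

    truth = {
        "ontology": {k: v for k, v in onto_truth.items() if k != "ids_by_level"},
        "expression": expr_truth,
        "proteomics": prot_truth,
        "profiles": prof_truth,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, default=str))
    paths["ground_truth"] = str(out / "ground_truth.json")
    return paths
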