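"""Synthetic (phospho)proteomics datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-condition replicate design on the log2-intensity scale,
Gaussian replicate noise, planted differential proteins, planted kinase
activity shifts propagated through a curated/predicted substrate network,
"protein-driven" phosphosite changes that mirror their parent protein's
fold-change, missing-at-random cells, per-site functional scores, gene-set
collections with planted enriched sets, and 4PL viability surfaces with a
known Bliss interaction.

Every stochastic draw derives from one global seed through named
``numpy.random.SeedSequence`` child streams (spawned in a fixed, documented
order), so identical ``(config, seed)`` pairs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    DoseResponseTable,
    FunctionalScoreTable,
    GeneSetCollection,
    KinaseSubstrateDB,
    QuantMatrix,
    SampleDesign,
)
from .synergy import four_pl

__all__ = [
    "PlantedKinase",
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "DoseResponseConfig",
    "DoseResponseTruth",
    "generate_dose_response",
]

# fixed spawn order of the per-stage random streams
_STREAMS = ["baseline", "structure", "effects", "network",
            "noise", "missing", "functional", "sets"]


@dataclass(frozen=True)
class PlantedKinase:
    """A kinase with a planted activity shift.

    ``delta`` is the log2 shift added to every substrate site in the
    conditions listed in ``active_in`` (default: every non-reference
    condition); ``n_substrates`` the number of substrate sites wired to it.
    """

    name: str
    delta: float
    n_substrates: int
    active_in: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_substrates < 1:
            raise ValueError("planted kinases need at least one substrate")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dataset generator.

    Defaults emulate a small TMT-style design: a reference and one case
    condition with 3 replicates each, log2 baselines around 25 ± 2,
    replicate noise SD 0.3, 5% differential proteins with |log2FC| uniform
    on [0.5, 2], and a 50-kinase substrate network whose predicted edges
    carry uniform [0, 10] scores so the score-3 retention filter bites.
    """

    n_proteins: int = 1000
    n_sites: int = 2000
    n_kinases: int = 50
    conditions: tuple[str, ...] = ("control", "case")
    reference_condition: str = "control"
    n_replicates: int = 3
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    site_offset_sd: float = 1.0
    noise_sd: float = 0.3
    frac_diff_proteins: float = 0.05
    effect_min: float = 0.5
    effect_max: float = 2.0
    planted_kinases: tuple[PlantedKinase, ...] = ()
    substrates_per_kinase: int = 8
    frac_protein_driven: float = 0.1
    missing_rate: float = 0.05
    frac_predicted_edges: float = 0.5
    predicted_score_max: float = 10.0
    n_gene_sets: int = 20
    gene_set_size: int = 25
    n_planted_sets: int = 1
    planted_set_purity: float = 0.8
    heavy_tailed_noise: bool = False   # Student-t (df 3) replicate noise
    mnar_missingness: bool = False     # intensity-dependent missingness

    def __post_init__(self) -> None:
        for name in ("frac_diff_proteins", "frac_protein_driven",
                     "missing_rate", "frac_predicted_edges",
                     "planted_set_purity"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.reference_condition not in self.conditions:
            raise ValueError("reference_condition must be one of conditions")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated dataset."""

    protein_log2fc: pd.Series            # nonzero entries = planted differential
    kinase_deltas: dict[str, float]
    kinase_substrates: dict[str, list[str]]
    kinase_active_in: dict[str, tuple[str, ...]]
    protein_driven_sites: dict[str, str] # site -> parent differential protein
    enriched_sets: list[str]
    seed: int

    @property
    def diff_proteins(self) -> list[str]:
        return self.protein_log2fc.index[self.protein_log2fc != 0].tolist()


@dataclass
class SyntheticDataset:
    proteome: QuantMatrix
    phospho: QuantMatrix
    ks_db: KinaseSubstrateDB
    functional_scores: FunctionalScoreTable
    gene_sets: GeneSetCollection
    design: SampleDesign
    truth: SyntheticTruth


def _noise(rng: np.random.Generator, shape, sd: float, heavy: bool) -> np.ndarray:
    if heavy:
        return rng.standard_t(df=3, size=shape) * sd
    return rng.normal(0.0, sd, size=shape)


def generate_dataset(config: GeneratorConfig, seed: int) -> SyntheticDataset:
    """Generate a proteome/phosphoproteome pair with planted truth.

    The value model on the log2 scale: a phosphosite intensity is its
    parent protein's baseline plus a site offset, plus the planted kinase
    shift δ_k in conditions where the kinase is active, plus the parent's
    planted fold-change for protein-driven sites, plus replicate noise;
    missingness is applied last.
    """
    rngs = {name: np.random.default_rng(child) for name, child in
            zip(_STREAMS, np.random.SeedSequence(seed).spawn(len(_STREAMS)))}

    total_planted_subs = sum(k.n_substrates for k in config.planted_kinases)
    if total_planted_subs > config.n_sites:
        raise ValueError(
            f"requested {total_planted_subs} planted substrate sites exceed "
            f"n_sites={config.n_sites}")

    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]
    baselines = pd.Series(
        rngs["baseline"].normal(config.baseline_mean, config.baseline_sd,
                                config.n_proteins),
        index=proteins)

    # --- site structure: parent protein, residue, unique position per protein
    rs = rngs["structure"]
    parents = rs.choice(proteins, size=config.n_sites, replace=True)
    residues = rs.choice(["S", "T", "Y"], size=config.n_sites, p=[0.84, 0.14, 0.02])
    sites: list[str] = []
    used: dict[str, set[int]] = {}
    for parent, res in zip(parents, residues):
        taken = used.setdefault(parent, set())
        pos = int(rs.integers(1, 2000))
        while pos in taken:
            pos = int(rs.integers(1, 2000))
        taken.add(pos)
        sites.append(f"{parent}_{res}{pos}")
    site_parent = pd.Series(parents, index=sites)

    # --- planted differential proteins
    re_ = rngs["effects"]
    n_diff = int(round(config.frac_diff_proteins * config.n_proteins))
    diff_proteins = list(re_.choice(proteins, size=n_diff, replace=False))
    protein_fc = pd.Series(0.0, index=proteins)
    if n_diff:
        magnitudes = re_.uniform(config.effect_min, config.effect_max, n_diff)
        signs = re_.choice([-1.0, 1.0], size=n_diff)
        protein_fc.loc[diff_proteins] = magnitudes * signs

    # --- protein-driven sites: re-parent a site fraction onto differential proteins
    protein_driven: dict[str, str] = {}
    n_driven = int(round(config.frac_protein_driven * config.n_sites))
    if n_driven and diff_proteins:
        driven_sites = re_.choice(sites, size=n_driven, replace=False)
        hosts = re_.choice(diff_proteins, size=n_driven, replace=True)
        for s, host in zip(driven_sites, hosts):
            protein_driven[str(s)] = str(host)

    # --- kinase-substrate network
    rn = rngs["network"]
    kinase_substrates: dict[str, list[str]] = {}
    kinase_deltas: dict[str, float] = {}
    kinase_active: dict[str, tuple[str, ...]] = {}
    non_ref = tuple(c for c in config.conditions if c != config.reference_condition)
    free_sites = [s for s in sites if s not in protein_driven]
    rn.shuffle(free_sites)
    cursor = 0
    edge_rows: list[tuple[str, str, str, float]] = []
    for pk in config.planted_kinases:
        chosen = free_sites[cursor:cursor + pk.n_substrates]
        if len(chosen) < pk.n_substrates:
            raise ValueError(
                f"not enough unassigned sites for planted kinase {pk.name}")
        cursor += pk.n_substrates
        kinase_substrates[pk.name] = chosen
        kinase_deltas[pk.name] = pk.delta
        kinase_active[pk.name] = pk.active_in if pk.active_in is not None else non_ref
        # curated edges so the planted truth survives the prediction-score filter
        edge_rows += [(pk.name, s, "curated", np.nan) for s in chosen]

    n_decoys = max(config.n_kinases - len(config.planted_kinases), 0)
    for i in range(n_decoys):
        name = f"KIN{i:03d}"
        m = int(rn.poisson(config.substrates_per_kinase)) + 1
        chosen = list(rn.choice(sites, size=min(m, len(sites)), replace=False))
        kinase_substrates[name] = chosen
        for s in chosen:
            if rn.random() < config.frac_predicted_edges:
                score = float(rn.uniform(0.0, config.predicted_score_max))
                edge_rows.append((name, s, "predicted", score))
            else:
                edge_rows.append((name, s, "curated", np.nan))
    ks_db = KinaseSubstrateDB(pd.DataFrame(
        edge_rows, columns=["kinase", "site", "source", "score"]))

    # --- sample design
    design_rows = []
    for cond in config.conditions:
        role = "control" if cond == config.reference_condition else "case"
        for r in range(1, config.n_replicates + 1):
            design_rows.append((f"{cond}_{r}", cond, r, role))
    design = SampleDesign(pd.DataFrame(
        design_rows, columns=["sample_id", "condition", "replicate", "group_role"]))
    sample_cond = dict(zip(design.sample_ids, design.table["condition"]))

    # --- deterministic expected values per (feature, condition)
    cond_is_case = {c: (c != config.reference_condition) for c in config.conditions}
    prot_expected = {
        c: baselines + (protein_fc if cond_is_case[c] else 0.0)
        for c in config.conditions
    }
    site_offset = pd.Series(
        rngs["structure"].normal(0.0, config.site_offset_sd, config.n_sites),
        index=sites)
    site_expected = {}
    for c in config.conditions:
        base = baselines.loc[site_parent].to_numpy() + site_offset.to_numpy()
        shift = np.zeros(config.n_sites)
        for kin, subs in kinase_substrates.items():
            if kin in kinase_deltas and c in kinase_active[kin]:
                idx = site_offset.index.get_indexer(subs)
                shift[idx] += kinase_deltas[kin]
        if cond_is_case[c] and protein_driven:
            for s, host in protein_driven.items():
                shift[site_offset.index.get_loc(s)] += protein_fc.loc[host]
        site_expected[c] = pd.Series(base + shift, index=sites)

    # --- noise and assembly
    rno = rngs["noise"]
    prot_data = {}
    site_data = {}
    for sample in design.sample_ids:
        c = sample_cond[sample]
        prot_data[sample] = (prot_expected[c].to_numpy()
                             + _noise(rno, config.n_proteins, config.noise_sd,
                                      config.heavy_tailed_noise))
        site_data[sample] = (site_expected[c].to_numpy()
                             + _noise(rno, config.n_sites, config.noise_sd,
                                      config.heavy_tailed_noise))
    proteome = pd.DataFrame(prot_data, index=proteins)
    phospho = pd.DataFrame(site_data, index=sites)

    # --- missingness (applied last)
    rm = rngs["missing"]

    def _apply_missing(frame: pd.DataFrame) -> pd.DataFrame:
        if config.missing_rate == 0:
            return frame
        if config.mnar_missingness:
            # lower-intensity cells are more likely to drop out
            centered = frame.to_numpy() - np.nanmean(frame.to_numpy())
            prob = np.clip(config.missing_rate * 2.0 / (1.0 + np.exp(centered)),
                           0.0, 1.0)
            mask = rm.random(frame.shape) < prob
        else:
            mask = rm.random(frame.shape) < config.missing_rate
        return frame.mask(pd.DataFrame(mask, index=frame.index,
                                       columns=frame.columns))

    proteome = _apply_missing(proteome)
    phospho = _apply_missing(phospho)

    functional = FunctionalScoreTable(pd.Series(
        rngs["functional"].uniform(0.0, 1.0, config.n_sites), index=sites))

    # --- gene sets over protein ids with planted enriched sets
    rg = rngs["sets"]
    sets: dict[str, set[str]] = {}
    enriched: list[str] = []
    for i in range(config.n_planted_sets):
        if not diff_proteins:
            break
        name = f"SET_PLANTED_{i:02d}"
        n_true = min(int(round(config.planted_set_purity * config.gene_set_size)),
                     len(diff_proteins))
        members = set(rg.choice(diff_proteins, size=n_true, replace=False))
        fill = [p for p in proteins if p not in members]
        members |= set(rg.choice(fill, size=config.gene_set_size - n_true,
                                 replace=False))
        sets[name] = members
        enriched.append(name)
    for i in range(config.n_gene_sets):
        sets[f"SET_{i:03d}"] = set(
            rg.choice(proteins, size=config.gene_set_size, replace=False))
    gene_sets = GeneSetCollection(sets)

    truth = SyntheticTruth(
        protein_log2fc=protein_fc,
        kinase_deltas=kinase_deltas,
        kinase_substrates=kinase_substrates,
        kinase_active_in=kinase_active,
        protein_driven_sites=protein_driven,
        enriched_sets=enriched,
        seed=seed,
    )
    return SyntheticDataset(
        proteome=QuantMatrix(proteome, "protein"),
        phospho=QuantMatrix(phospho, "phosphosite"),
        ks_db=ks_db,
        functional_scores=functional,
        gene_sets=gene_sets,
        design=design,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# dose-response surfaces


@dataclass(frozen=True)
class DoseResponseConfig:
    """True 4PL parameters per agent and the planted Bliss interaction.

    ``epsilon`` shifts the combination surviving fraction below (> 0,
    synergy) or above (< 0, antagonism) the Bliss-independent product.
    """

    params_a: tuple[float, float, float, float] = (0.0, 1.0, 1.0, 1.0)
    params_b: tuple[float, float, float, float] = (0.0, 1.0, 2.0, 1.0)
    doses_a: tuple[float, ...] = tuple(float(d) for d in np.logspace(-2, 2, 8))
    doses_b: tuple[float, ...] = tuple(float(d) for d in np.logspace(-2, 2, 8))
    n_replicates: int = 3
    noise_sd: float = 0.05
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses_a + self.doses_b):
            raise ValueError("doses must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class DoseResponseTruth:
    params_a: tuple[float, float, float, float]
    params_b: tuple[float, float, float, float]
    epsilon: float
    seed: int


def generate_dose_response(
    config: DoseResponseConfig, seed: int
) -> tuple[dict[str, DoseResponseTable], pd.DataFrame, DoseResponseTruth]:
    """Replicate single-agent plates and a combination surface.

    The combination surviving fraction at each dose pair is
    S_A·S_B − ε + noise (clipped at 0).  Returns single-agent tables keyed
    "A"/"B", a combination frame (dose_a, dose_b, response, replicate) and
    the planted truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    singles: dict[str, DoseResponseTable] = {}
    for agent, params, doses in (("A", config.params_a, config.doses_a),
                                 ("B", config.params_b, config.doses_b)):
        rows = []
        for rep in range(1, config.n_replicates + 1):
            resp = four_pl(np.array(doses), *params)
            resp = np.clip(resp + rng.normal(0, config.noise_sd, len(doses)), 0, None)
            rows += [(d, r, rep) for d, r in zip(doses, resp)]
        singles[agent] = DoseResponseTable(
            pd.DataFrame(rows, columns=["dose", "response", "replicate"]),
            agent=agent)

    sa = four_pl(np.array(config.doses_a), *config.params_a)
    sb = four_pl(np.array(config.doses_b), *config.params_b)
    combo_rows = []
    for rep in range(1, config.n_replicates + 1):
        for i, da in enumerate(config.doses_a):
            for j, db in enumerate(config.doses_b):
                s_ab = sa[i] * sb[j] - config.epsilon
                s_ab += rng.normal(0, config.noise_sd) if config.noise_sd else 0.0
                combo_rows.append((da, db, max(s_ab, 0.0), rep))
    combination = pd.DataFrame(
        combo_rows, columns=["dose_a", "dose_b", "response", "replicate"])
    truth = DoseResponseTruth(config.params_a, config.params_b, config.epsilon, seed)
    return singles, combination, truth
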