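"""Config-driven orchestration of the full analysis graph.

A run takes either user-supplied TSV/GMT inputs or a synthetic-data
generator block, then executes: completeness filter → per-sample median
centering → one significance test per configured comparison (SAM-style
two-class, one-way ANOVA, or one-sample t on ratios) → volcano selection
with proteome-level correction and functional-score prioritization → KSEA
per comparison → cross-comparison kinase signature with k-means row
clustering → over-representation analysis of the selected proteins →
optional connectivity-query list export and dose-response/synergy analysis.

Every output TSV is stamped with the config hash and seed; rerunning with
identical config and seed reproduces every file checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diffstats, enrich, ksea, preprocess, synergy as synmod
from .io import (
    FunctionalScoreTable,
    GeneSetCollection,
    QuantMatrix,
    SampleDesign,
    read_design,
    read_functional_scores,
    read_gene_sets,
    read_ks_db,
    read_quant_matrix,
)
from .synth import (
    DoseResponseConfig,
    GeneratorConfig,
    PlantedKinase,
    SyntheticDataset,
    generate_dataset,
    generate_dose_response,
)

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    seed: int
    output_dir: str
    comparisons: list[dict] = field(default_factory=list)
    generator: dict | None = None         # GeneratorConfig fields
    data: dict | None = None              # paths: proteome, phospho, design, ...
    min_per_group: int | None = None      # completeness filter, None = off
    normalize: bool = True
    volcano: dict = field(default_factory=lambda: {"fdr": 0.01, "functional_min": 0.5})
    ksea: dict = field(default_factory=lambda: {
        "networkin_min": 3.0, "min_substrates": 4, "q_cut": 0.05,
        "min_significant": 3, "k": 3})
    enrichment: dict = field(default_factory=lambda: {"top_n": 100})
    connectivity: dict = field(default_factory=lambda: {"top_n": 150})
    synergy: dict | None = None           # DoseResponseConfig fields

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _generator_config(block: dict) -> GeneratorConfig:
    block = dict(block)
    planted = tuple(
        PlantedKinase(
            name=pk["name"], delta=float(pk["delta"]),
            n_substrates=int(pk["n_substrates"]),
            active_in=tuple(pk["active_in"]) if pk.get("active_in") else None)
        for pk in block.pop("planted_kinases", []))
    if "conditions" in block:
        block["conditions"] = tuple(block["conditions"])
    return GeneratorConfig(planted_kinases=planted, **block)


def validate_config(config: RunConfig) -> list[str]:
    """Static validation; returns violations instead of raising."""
    violations: list[str] = []
    if (config.generator is None) == (config.data is None):
        violations.append("exactly one of 'generator' and 'data' must be set")
    conditions: set[str] | None = None
    if config.generator is not None:
        try:
            gen = _generator_config(config.generator)
            conditions = set(gen.conditions)
        except (ValueError, TypeError) as exc:
            violations.append(f"generator: {exc}")
    if config.data is not None:
        for key in ("proteome", "phospho", "design", "ks_db"):
            path = config.data.get(key)
            if path is None:
                violations.append(f"data: missing required path '{key}'")
            elif not Path(path).exists():
                violations.append(f"data: file not found: {path}")
        design_path = config.data.get("design")
        if design_path and Path(design_path).exists():
            conditions = set(read_design(design_path).conditions)
    if not config.comparisons:
        violations.append("no comparisons configured")
    names = [c.get("name") for c in config.comparisons]
    if len(names) != len(set(names)):
        violations.append("duplicate comparison names")
    for comp in config.comparisons:
        name = comp.get("name", "<unnamed>")
        test = comp.get("test", "sam")
        if test not in ("sam", "anova", "one_sample"):
            violations.append(f"comparison {name}: unknown test {test!r}")
        fdr = comp.get("fdr", 0.05)
        if not (0.0 < fdr < 1.0):
            violations.append(f"comparison {name}: fdr {fdr} outside (0, 1)")
        if conditions is not None:
            for role in ("case", "control"):
                cond = comp.get(role)
                if cond is not None and cond not in conditions:
                    violations.append(
                        f"comparison {name}: unknown condition {cond!r}")
    for key in ("fdr", "functional_min"):
        val = config.volcano.get(key)
        if val is not None and not (0.0 <= val <= 1.0):
            violations.append(f"volcano.{key} outside [0, 1]")
    if config.ksea.get("min_substrates", 4) < 1:
        violations.append("ksea.min_substrates must be >= 1")
    if config.synergy is not None:
        try:
            DoseResponseConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in config.synergy.items()})
        except (ValueError, TypeError) as exc:
            violations.append(f"synergy: {exc}")
    return violations


def _load_inputs(config: RunConfig) -> SyntheticDataset:
    if config.generator is not None:
        return generate_dataset(_generator_config(config.generator), config.seed)
    paths = config.data
    design = read_design(paths["design"])
    proteome = read_quant_matrix(paths["proteome"], design, "protein")
    phospho = read_quant_matrix(paths["phospho"], design, "phosphosite")
    ks_db = read_ks_db(paths["ks_db"])
    functional = (read_functional_scores(paths["functional_scores"])
                  if paths.get("functional_scores") else FunctionalScoreTable({}))
    gene_sets = (read_gene_sets(paths["gene_sets"])
                 if paths.get("gene_sets") else GeneSetCollection({}))
    return SyntheticDataset(proteome, phospho, ks_db, functional, gene_sets,
                            design, truth=None)  # type: ignore[arg-type]


class _Writer:
    """Writes stamped TSV outputs and tracks checksums for the run report."""

    def __init__(self, out_dir: Path, config_hash: str, seed: int) -> None:
        self.out_dir = out_dir
        self.stamp = f"# kinsig config_hash={config_hash} seed={seed}\n"
        self.files: dict[str, str] = {}

    def write_frame(self, frame: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = self.out_dir / name
        with open(path, "w") as fh:
            fh.write(self.stamp)
            frame.to_csv(fh, sep="\t", index=index)
        self._record(path)
        return path

    def write_lines(self, lines: list[str], name: str) -> Path:
        path = self.out_dir / name
        with open(path, "w") as fh:
            fh.write(self.stamp)
            fh.write("\n".join(lines) + ("\n" if lines else ""))
        self._record(path)
        return path

    def _record(self, path: Path) -> None:
        digest = hashlib.md5(path.read_bytes()).hexdigest()
        self.files[path.name] = digest


def _site_parent(site: str) -> str:
    return site.rsplit("_", 1)[0]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis; returns the run report dict.

    Any stage error aborts with :class:`PipelineError` naming the stage.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writer = _Writer(out_dir, config.config_hash, config.seed)
    report: dict[str, Any] = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str):
        report["stages"][name] = {}
        return report["stages"][name]

    # ---- inputs
    log = stage("inputs")
    try:
        ds = _load_inputs(config)
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc
    log["n_proteins"] = ds.proteome.shape[0]
    log["n_sites"] = ds.phospho.shape[0]
    log["n_samples"] = len(ds.design.sample_ids)

    used_conditions = sorted({c[r] for c in config.comparisons
                              for r in ("case", "control") if c.get(r)})

    # ---- completeness filter
    proteome, phospho = ds.proteome, ds.phospho
    if config.min_per_group is not None:
        log = stage("completeness_filter")
        try:
            proteome = preprocess.filter_by_completeness(
                proteome, ds.design, config.min_per_group, used_conditions or None)
            phospho = preprocess.filter_by_completeness(
                phospho, ds.design, config.min_per_group, used_conditions or None)
        except Exception as exc:
            raise PipelineError("completeness_filter", str(exc)) from exc
        log["proteins_kept"] = proteome.shape[0]
        log["sites_kept"] = phospho.shape[0]

    # ---- normalization
    if config.normalize:
        log = stage("normalize")
        try:
            proteome, prot_report = preprocess.normalize_median_center(proteome)
            phospho, _ = preprocess.normalize_median_center(phospho)
        except Exception as exc:
            raise PipelineError("normalize", str(exc)) from exc
        log["method"] = prot_report.method

    # ---- per-comparison tests
    prot_results: dict[str, pd.DataFrame] = {}
    site_results: dict[str, pd.DataFrame] = {}
    for comp in config.comparisons:
        name = comp["name"]
        log = stage(f"test:{name}")
        try:
            prot_results[name] = _run_test(proteome, ds.design, comp, config.seed)
            site_results[name] = _run_test(phospho, ds.design, comp, config.seed)
        except Exception as exc:
            raise PipelineError(f"test:{name}", str(exc)) from exc
        log["test"] = comp.get("test", "sam")
        log["significant_proteins"] = int(prot_results[name]["significant"].sum())
        log["significant_sites"] = int(site_results[name]["significant"].sum())
        writer.write_frame(prot_results[name], f"diff_proteome_{name}.tsv")
        writer.write_frame(site_results[name], f"diff_phospho_{name}.tsv")

    # ---- volcano + proteome correction + functional prioritization
    vol_cfg = config.volcano
    for name in site_results:
        log = stage(f"volcano:{name}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = diffstats.volcano_select(site_results[name],
                                               fdr=vol_cfg.get("fdr", 0.01))
                prot_sel = diffstats.volcano_select(prot_results[name],
                                                    fdr=vol_cfg.get("fdr", 0.01))
            mapping = {s: _site_parent(s) for s in sel.table.index}
            sel = diffstats.proteome_correction_flags(sel, mapping, prot_sel)
            sel = diffstats.prioritize_functional(
                sel, ds.functional_scores,
                min_score=vol_cfg.get("functional_min", 0.5))
        except Exception as exc:
            raise PipelineError(f"volcano:{name}", str(exc)) from exc
        log["selected_sites"] = len(sel.selected)
        log["prioritized_sites"] = len(sel.prioritized)
        writer.write_frame(sel.table, f"volcano_{name}.tsv")

    # ---- KSEA per comparison
    kcfg = config.ksea
    expanded = ksea.expand_ks_db(ds.ks_db, kcfg.get("networkin_min", 3.0))
    score_tables: dict[str, pd.DataFrame] = {}
    for name in site_results:
        log = stage(f"ksea:{name}")
        try:
            scores = ksea.ksea_scores(site_results[name]["log2fc"], expanded,
                                      min_substrates=kcfg.get("min_substrates", 4))
        except Exception as exc:
            raise PipelineError(f"ksea:{name}", str(exc)) from exc
        score_tables[name] = scores
        log["kinases_scored"] = len(scores)
        log["kinases_significant"] = int((scores["q"] < kcfg.get("q_cut", 0.05)).sum())
        writer.write_frame(scores, f"ksea_{name}.tsv")

    # ---- signature + k-means
    signature = None
    if len(score_tables) >= 2:
        log = stage("signature")
        try:
            signature = ksea.cross_comparison_signature(
                score_tables,
                min_significant=kcfg.get("min_significant", 3),
                q_cut=kcfg.get("q_cut", 0.05))
            k = kcfg.get("k", 3)
            if len(signature.z) >= k:
                signature = ksea.kmeans_rows(signature, k=k, seed=config.seed)
                log["clustered"] = True
            else:
                log["clustered"] = False
        except Exception as exc:
            raise PipelineError("signature", str(exc)) from exc
        log["kinases_retained"] = len(signature.z)
        writer.write_frame(signature.to_long(), "signature_long.tsv", index=False)
        writer.write_frame(signature.z, "signature_z.tsv")

    # ---- over-representation of selected proteins per comparison
    if len(ds.gene_sets):
        for name, res in prot_results.items():
            log = stage(f"ora:{name}")
            background = res.index[res["log2fc"].notna()].tolist()
            foreground = res.index[res["significant"]].tolist()
            if not foreground:
                log["skipped"] = "empty foreground"
                continue
            try:
                enr = enrich.ora_fisher(foreground, ds.gene_sets, background)
            except Exception as exc:
                raise PipelineError(f"ora:{name}", str(exc)) from exc
            log["sets_tested"] = len(enr)
            writer.write_frame(enr, f"ora_{name}.tsv")

    # ---- connectivity query lists
    ccfg = config.connectivity
    for name, res in prot_results.items():
        if res["statistic"].notna().sum() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lists = enrich.rank_and_select_top(
                res, rank_by="statistic", n=ccfg.get("top_n", 150), side="both")
        writer.write_lines(lists["up"], f"query_up_{name}.txt")
        writer.write_lines(lists["down"], f"query_down_{name}.txt")

    # ---- synergy
    if config.synergy is not None:
        log = stage("synergy")
        try:
            dr_cfg = DoseResponseConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in config.synergy.items()})
            singles, combination, truth = generate_dose_response(dr_cfg, config.seed)
            fits = {agent: synmod.fit_4pl(tab) for agent, tab in singles.items()}
            surface = synmod.bliss_surface(singles["A"], singles["B"], combination)
        except Exception as exc:
            raise PipelineError("synergy", str(exc)) from exc
        log["ic50"] = {a: f.ic50 for a, f in fits.items()}
        log["mean_bliss_index"] = float(surface["bliss_index"].mean())
        writer.write_frame(surface, "bliss_surface.tsv", index=False)

    report["files"] = writer.files
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _run_test(matrix: QuantMatrix, design: SampleDesign, comp: dict,
              seed: int) -> pd.DataFrame:
    test = comp.get("test", "sam")
    fdr = comp.get("fdr", 0.05)
    s0 = comp.get("s0", 0.1)
    if test == "sam":
        params = diffstats.SamParams(
            s0=s0, n_permutations=comp.get("n_permutations", 250),
            fdr_target=fdr, seed=seed)
        return diffstats.sam_test(matrix, design, comp["case"], comp["control"],
                                  params)
    if test == "anova":
        conds = comp.get("conditions")
        return diffstats.anova_oneway(matrix, design, conds, fdr=fdr)
    if test == "one_sample":
        ratios = preprocess.make_log2_ratios_vs_reference(
            matrix, design, comp["control"], [comp["case"]])
        return diffstats.one_sample_t(ratios, s0=s0, fdr=fdr)
    raise ValueError(f"unknown test {test!r}")
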