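"""Domain types and tab-separated readers/writers shared by all pipeline stages.

The pipeline works on log2-intensity quantification matrices (proteome or
phosphoproteome), a sample-design table, a kinase–substrate edge table
(curated relationships plus score-bearing predictions), per-site functional
scores, gene-set collections (GMT) and dose–response plate tables.

All tabular formats are TSV with a header row, decimal point, no thousands
separators.  Missing values are written as empty cells and read from empty
cells or the token ``NA``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "QuantMatrix",
    "PhosphoSiteKey",
    "KinaseSubstrateDB",
    "FunctionalScoreTable",
    "GeneSetCollection",
    "DoseResponseTable",
    "parse_site_key",
    "format_site_key",
    "read_design",
    "read_quant_matrix",
    "write_quant_matrix",
    "read_ks_db",
    "write_ks_db",
    "read_functional_scores",
    "write_functional_scores",
    "read_gene_sets",
    "write_gene_sets",
    "read_dose_response",
    "write_dose_response",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}
_GROUP_ROLES = {"case", "control", "other"}


# ---------------------------------------------------------------------------
# sample design


@dataclass
class SampleDesign:
    """Maps samples to experimental conditions.

    ``table`` has columns ``sample_id``, ``condition``, ``replicate`` and
    ``group_role`` (one of case/control/other).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "replicate", "group_role"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        tab = self.table[required].copy()
        tab["sample_id"] = tab["sample_id"].astype(str)
        tab["condition"] = tab["condition"].astype(str)
        tab["replicate"] = tab["replicate"].astype(int)
        if tab["sample_id"].duplicated().any():
            dups = tab.loc[tab["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in design: {dups}")
        if (tab["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        bad = set(tab["group_role"]) - _GROUP_ROLES
        if bad:
            raise ValueError(f"unknown group_role values: {sorted(bad)}")
        self.table = tab.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def samples(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in design order."""
        sel = self.table["condition"] == condition
        if not sel.any():
            raise KeyError(f"condition {condition!r} not in design")
        return self.table.loc[sel, "sample_id"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t", dtype=str).assign(
        replicate=lambda t: t["replicate"].astype(int)))


# ---------------------------------------------------------------------------
# quantification matrix


class QuantMatrix:
    """Features × samples table of log2 intensities; NaN marks missing.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample.
    feature_kind
        ``"protein"`` or ``"phosphosite"``.
    """

    def __init__(self, data: pd.DataFrame, feature_kind: str = "protein") -> None:
        if feature_kind not in ("protein", "phosphosite"):
            raise ValueError(f"unknown feature_kind {feature_kind!r}")
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        values = data.to_numpy(dtype=float, na_value=np.nan)
        if np.isinf(values).any():
            raise ValueError("matrix contains non-finite (inf) values")
        self.data = pd.DataFrame(values, index=data.index.astype(str),
                                 columns=data.columns.astype(str))
        self.feature_kind = feature_kind

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "QuantMatrix":
        return QuantMatrix(self.data[list(sample_ids)], self.feature_kind)

    def __repr__(self) -> str:  # pragma: no cover
        r, c = self.shape
        return f"QuantMatrix({self.feature_kind}, {r} features x {c} samples)"


def read_quant_matrix(
    path: str | Path,
    design: SampleDesign | None = None,
    feature_kind: str = "protein",
    raw: bool = False,
) -> QuantMatrix:
    """Read a features × samples TSV (first column = feature id).

    ``raw=True`` declares linear-scale intensities: they are log2-transformed
    on read (non-positive entries become missing).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip",
                     na_values=list(_MISSING_TOKENS), keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature {dup!r} in {path}")
    if design is not None:
        absent = [s for s in design.sample_ids if s not in df.columns]
        if absent:
            raise ValueError(f"samples in design absent from {path}: {absent}")
        df = df[design.sample_ids]
    if raw:
        vals = df.to_numpy(dtype=float)
        out = np.full_like(vals, np.nan)
        np.log2(vals, out=out, where=vals > 0)
        df = pd.DataFrame(out, index=df.index, columns=df.columns)
    return QuantMatrix(df, feature_kind=feature_kind)


def write_quant_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "feature_id"
    # repr-precision floats round-trip bit-identically
    out.to_csv(path, sep="\t", na_rep="", float_format=None)


# ---------------------------------------------------------------------------
# phosphosite keys


_SITE_RE = re.compile(r"^(?P<protein>.+)_(?P<residue>[A-Z])(?P<position>\d+)$")


@dataclass(frozen=True, order=True)
class PhosphoSiteKey:
    """A phosphorylated residue: protein, residue letter (S/T/Y), 1-based position."""

    protein_id: str
    residue: str
    position: int
    localization_prob: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"residue must be S, T or Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.localization_prob is not None and not (0.0 <= self.localization_prob <= 1.0):
            raise ValueError("localization_prob must lie in [0, 1]")

    @property
    def is_class_one(self) -> bool:
        """Class-I site: localization probability above 0.75."""
        return self.localization_prob is not None and self.localization_prob > 0.75

    def __str__(self) -> str:
        return format_site_key(self)


def parse_site_key(text: str) -> PhosphoSiteKey:
    """Parse ``"PROTEIN_S123"`` into a :class:`PhosphoSiteKey`."""
    m = _SITE_RE.match(text)
    if m is None:
        raise ValueError(f"malformed site key {text!r}; expected PROTEIN_S123")
    return PhosphoSiteKey(m["protein"], m["residue"], int(m["position"]))


def format_site_key(key: PhosphoSiteKey) -> str:
    return f"{key.protein_id}_{key.residue}{key.position}"


# ---------------------------------------------------------------------------
# kinase-substrate database


class KinaseSubstrateDB:
    """Kinase → substrate-site edge list.

    Edges are either ``curated`` (no score) or ``predicted`` (carry a
    non-negative prediction score, e.g. a NetworKIN score).  Duplicate
    (kinase, site) pairs are collapsed on construction; when a pair occurs
    both curated and predicted the curated edge wins.
    """

    COLUMNS = ["kinase", "site", "source", "score"]

    def __init__(self, edges: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        tab = edges[self.COLUMNS].copy()
        tab["kinase"] = tab["kinase"].astype(str)
        tab["site"] = tab["site"].astype(str)
        tab["score"] = pd.to_numeric(tab["score"], errors="coerce")
        bad_source = set(tab["source"]) - {"curated", "predicted"}
        if bad_source:
            raise ValueError(f"unknown edge source: {sorted(bad_source)}")
        pred = tab["source"] == "predicted"
        if tab.loc[pred, "score"].isna().any():
            rows = tab.loc[pred & tab["score"].isna(), ["kinase", "site"]]
            raise ValueError(
                f"predicted edge without score: {rows.iloc[0].tolist()}")
        if (tab.loc[pred, "score"] < 0).any():
            raise ValueError("prediction scores must be non-negative")
        tab.loc[~pred, "score"] = np.nan  # curated edges carry no score
        for s in tab["site"]:
            parse_site_key(s)  # validates the site dialect
        # dedup: curated wins; among predicted duplicates keep the top score
        tab = tab.sort_values(
            ["kinase", "site", "source", "score"],
            ascending=[True, True, True, False], kind="mergesort")
        tab = tab.drop_duplicates(["kinase", "site"], keep="first")
        self.edges = tab.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    def substrates(self, kinase: str) -> list[str]:
        return self.edges.loc[self.edges["kinase"] == kinase, "site"].tolist()

    @property
    def kinases(self) -> list[str]:
        return sorted(self.edges["kinase"].unique())

    def to_tsv(self, path: str | Path) -> None:
        out = self.edges.copy()
        out.to_csv(path, sep="\t", index=False, na_rep="")


def read_ks_db(path: str | Path) -> KinaseSubstrateDB:
    tab = pd.read_csv(path, sep="\t", dtype={"kinase": str, "site": str, "source": str},
                      na_values=list(_MISSING_TOKENS), keep_default_na=False)
    return KinaseSubstrateDB(tab)


def write_ks_db(db: KinaseSubstrateDB, path: str | Path) -> None:
    db.to_tsv(path)


# ---------------------------------------------------------------------------
# functional scores


class FunctionalScoreTable:
    """Site → functional-relevance score in [0, 1]."""

    def __init__(self, scores: Mapping[str, float] | pd.Series) -> None:
        ser = pd.Series(scores, dtype=float)
        ser.index = ser.index.astype(str)
        if ser.index.duplicated().any():
            raise ValueError("duplicate sites in functional score table")
        if ((ser < 0) | (ser > 1)).any():
            raise ValueError("functional scores must lie in [0, 1]")
        self.scores = ser

    def __len__(self) -> int:
        return len(self.scores)

    def get(self, site: str) -> float | None:
        val = self.scores.get(site)
        return None if val is None or pd.isna(val) else float(val)

    def to_tsv(self, path: str | Path) -> None:
        out = self.scores.rename("functional_score").rename_axis("site")
        out.to_csv(path, sep="\t")


def read_functional_scores(path: str | Path) -> FunctionalScoreTable:
    tab = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return FunctionalScoreTable(tab.iloc[:, 0])


def write_functional_scores(table: FunctionalScoreTable, path: str | Path) -> None:
    table.to_tsv(path)


# ---------------------------------------------------------------------------
# gene sets (GMT)


class GeneSetCollection:
    """Named gene sets, optionally tagged with a category per set."""

    def __init__(self, sets: Mapping[str, Iterable[str]],
                 descriptions: Mapping[str, str] | None = None,
                 categories: Mapping[str, str] | None = None) -> None:
        self.sets: dict[str, frozenset[str]] = {}
        for name, members in sets.items():
            if not str(name):
                raise ValueError("empty gene-set name")
            self.sets[str(name)] = frozenset(str(m) for m in members)
        self.descriptions = dict(descriptions or {})
        self.categories = dict(categories or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            name, desc, members = parts[0], parts[1] if len(parts) > 1 else "", parts[2:]
            members = [m for m in members if m.strip()]
            if not members:
                warnings.warn(f"gene set {name!r} (line {lineno}) has no members; skipped")
                continue
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    collection.to_gmt(path)


# ---------------------------------------------------------------------------
# dose-response plates


class DoseResponseTable:
    """Replicated viability measurements over a dose series for one agent.

    ``table`` columns: ``dose`` (µM, > 0), ``response`` (surviving fraction
    relative to vehicle, ≥ 0), ``replicate``.
    """

    def __init__(self, table: pd.DataFrame, agent: str = "") -> None:
        required = ["dose", "response", "replicate"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"dose-response table missing columns: {missing}")
        tab = table[required].copy()
        tab["dose"] = tab["dose"].astype(float)
        tab["response"] = tab["response"].astype(float)
        if (tab["dose"] <= 0).any():
            raise ValueError("doses must be positive")
        if (tab["response"] < 0).any():
            raise ValueError("responses must be non-negative")
        self.table = tab.reset_index(drop=True)
        self.agent = agent

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.table["dose"].unique())

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "agent", self.agent)
        out.to_csv(path, sep="\t", index=False)


def read_dose_response(path: str | Path) -> dict[str, DoseResponseTable]:
    """Read a plate TSV with columns agent, dose, response, replicate."""
    tab = pd.read_csv(path, sep="\t")
    if "agent" not in tab.columns:
        tab["agent"] = ""
    return {
        str(agent): DoseResponseTable(sub, agent=str(agent))
        for agent, sub in tab.groupby("agent", sort=True)
    }


def write_dose_response(tables: Mapping[str, DoseResponseTable], path: str | Path) -> None:
    frames = []
    for agent, tab in tables.items():
        out = tab.table.copy()
        out.insert(0, "agent", agent)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
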