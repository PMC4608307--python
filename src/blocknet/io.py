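"""Core data types and readers/writers for all external table formats.

Formats handled here: expression matrix TSV (genes x samples), sample
sheet TSV, GMT / two-column annotation files, edge-list TSV, and Pajek
``.net`` export.  All tables are UTF-8 TSV with a header row, ``.``
decimal separator and ``NA`` as the missing-value token.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical stimulation-condition vocabulary, in factor order.
CONDITIONS: tuple[str, ...] = ("medium", "IgG", "IL12", "IgG_IL12")

#: Built-in synonym map (keys are lower-cased before lookup).
DEFAULT_SYNONYMS: dict[str, str] = {
    "medium": "medium",
    "media": "medium",
    "none": "medium",
    "unstimulated": "medium",
    "igg": "IgG",
    "fcr": "IgG",
    "il12": "IL12",
    "il-12": "IL12",
    "igg_il12": "IgG_IL12",
    "igg+il12": "IgG_IL12",
    "igg-il12": "IgG_IL12",
    "igg il12": "IgG_IL12",
    "il12+igg": "IgG_IL12",
    "combo": "IgG_IL12",
}

MISSING = "NA"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


class ValidationError(ValueError):
    """Semantically invalid data (bad labels, incomplete design, ...)."""


def canonical_condition(label: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Map a raw condition label onto the canonical 4-level vocabulary.

    Raises :class:`ValidationError` for labels with no known synonym.
    """
    table = dict(DEFAULT_SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    key = str(label).strip().lower()
    if key not in table:
        raise ValidationError(
            f"unknown condition label {label!r}; expected one of {CONDITIONS} "
            "or a configured synonym"
        )
    value = table[key]
    if value not in CONDITIONS:
        raise ValidationError(f"synonym {label!r} maps to unknown condition {value!r}")
    return value


@dataclass
class ExpressionStudy:
    """Gene x sample intensity matrix plus the blocked factorial design.

    ``intensities`` is a ``(n_genes, n_samples)`` float array of
    linear-scale expression estimates.  ``design`` is indexed by sample
    id with columns ``donor``, ``condition``, ``replicate``.
    """

    genes: list[str]
    samples: list[str]
    intensities: np.ndarray
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        if self.intensities.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("non-finite intensity values")
        missing = set(self.samples) - set(self.design.index)
        extra = set(self.design.index) - set(self.samples)
        if missing or extra:
            raise FormatError(
                f"sample sheet mismatch: missing from sheet {sorted(missing)}, "
                f"not in matrix {sorted(extra)}"
            )
        for col in ("donor", "condition", "replicate"):
            if col not in self.design.columns:
                raise FormatError(f"sample sheet lacks required column {col!r}")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"non-canonical condition labels: {sorted(bad)}")

    # -- convenience --------------------------------------------------
    @property
    def donors(self) -> list[str]:
        return sorted(set(self.design["donor"].astype(str)))

    @property
    def conditions(self) -> list[str]:
        present = set(self.design["condition"])
        return [c for c in CONDITIONS if c in present]

    def is_complete(self) -> bool:
        """True when every donor has at least one sample of all 4 conditions."""
        cells = set(zip(self.design["donor"].astype(str), self.design["condition"]))
        return all((d, c) in cells for d in self.donors for c in CONDITIONS)

    def sample_ids(self, donor: str, condition: str) -> list[str]:
        mask = (self.design["donor"].astype(str) == str(donor)) & (
            self.design["condition"] == condition
        )
        return list(self.design.index[mask])

    def column(self, sample_id: str) -> np.ndarray:
        return self.intensities[:, self.samples.index(sample_id)]

    def floor(self, min_intensity: float = 1.0) -> "ExpressionStudy":
        """Clamp intensities below ``min_intensity`` up to it (new study)."""
        clamped = np.maximum(self.intensities, float(min_intensity))
        return ExpressionStudy(
            genes=list(self.genes),
            samples=list(self.samples),
            intensities=clamped,
            design=self.design.copy(),
        )


def read_expression_study(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    synonyms: Mapping[str, str] | None = None,
) -> ExpressionStudy:
    """Read an expression matrix TSV and its sample sheet.

    The matrix has a header row of sample ids and a first column of gene
    ids; the sheet has columns ``sample_id``, ``donor``, ``condition``,
    ``replicate``.  Condition labels are canonicalized.
    """
    matrix = pd.read_csv(
        matrix_path, sep="\t", index_col=0, na_values=[MISSING], float_precision="round_trip"
    )
    if matrix.isna().any().any():
        rows, cols = np.nonzero(matrix.isna().to_numpy())
        loc = (matrix.index[rows[0]], matrix.columns[cols[0]])
        raise FormatError(f"non-numeric or missing cell at gene {loc[0]!r}, sample {loc[1]!r}")
    try:
        values = matrix.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {matrix_path}: {exc}") from exc

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "donor", "condition", "replicate"}
    if not required <= set(sheet.columns):
        raise FormatError(
            f"sample sheet must have columns {sorted(required)}; got {list(sheet.columns)}"
        )
    sheet = sheet.set_index("sample_id")
    sheet["condition"] = [canonical_condition(c, synonyms) for c in sheet["condition"]]
    sheet["replicate"] = sheet["replicate"].astype(int)
    if (sheet["replicate"] < 1).any():
        raise ValidationError("replicate numbers must be positive integers")

    return ExpressionStudy(
        genes=[str(g) for g in matrix.index],
        samples=[str(s) for s in matrix.columns],
        intensities=values,
        design=sheet,
    )


def write_expression_study(
    study: ExpressionStudy, matrix_path: str | Path, sample_sheet_path: str | Path
) -> None:
    matrix = pd.DataFrame(study.intensities, index=study.genes, columns=study.samples)
    matrix.index.name = "gene"
    matrix.to_csv(matrix_path, sep="\t", float_format="%.17g", na_rep=MISSING)
    sheet = study.design.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sample_sheet_path, sep="\t", na_rep=MISSING)


def collapse_replicates(study: ExpressionStudy, method: str = "mean") -> ExpressionStudy:
    """Collapse replicate samples to one profile per (donor, condition).

    Replicates are averaged in the linear intensity scale; single-replicate
    cells pass through unchanged.  The collapsed sample keeps the id of the
    first replicate and ``replicate`` is set to 1.
    """
    if method != "mean":
        raise ValueError(f"unsupported collapse method {method!r}")
    new_samples: list[str] = []
    new_cols: list[np.ndarray] = []
    new_rows: list[dict] = []
    seen = set()
    for sid in study.samples:
        donor = str(study.design.at[sid, "donor"])
        cond = study.design.at[sid, "condition"]
        if (donor, cond) in seen:
            continue
        seen.add((donor, cond))
        ids = study.sample_ids(donor, cond)
        cols = study.intensities[:, [study.samples.index(i) for i in ids]]
        new_samples.append(ids[0])
        new_cols.append(cols.mean(axis=1))
        new_rows.append({"sample_id": ids[0], "donor": donor, "condition": cond, "replicate": 1})
    design = pd.DataFrame(new_rows).set_index("sample_id")
    return ExpressionStudy(
        genes=list(study.genes),
        samples=new_samples,
        intensities=np.column_stack(new_cols),
        design=design,
    )


def replicate_concordance(study: ExpressionStudy) -> tuple[pd.DataFrame, float]:
    """Squared Pearson correlation between duplicate profiles per cell.

    Returns one row per (donor, condition) with exactly two replicates
    plus the mean r-squared over those rows.  Cells with a replicate
    count other than two are skipped with a warning; zero-variance
    vectors yield a missing r-squared.
    """
    rows = []
    for donor in study.donors:
        for cond in study.conditions:
            ids = study.sample_ids(donor, cond)
            if len(ids) != 2:
                warnings.warn(
                    f"cell ({donor}, {cond}) has {len(ids)} replicates, expected 2; skipped"
                )
                continue
            x, y = study.column(ids[0]), study.column(ids[1])
            if np.std(x) == 0 or np.std(y) == 0:
                r2 = np.nan
                warnings.warn(f"zero-variance replicate in cell ({donor}, {cond})")
            else:
                r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
            rows.append({"donor": donor, "condition": cond, "r_squared": r2})
    table = pd.DataFrame(rows, columns=["donor", "condition", "r_squared"])
    mean_r2 = float(table["r_squared"].mean()) if len(table) else float("nan")
    return table, mean_r2


# ---------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------


@dataclass
class AnnotationCatalog:
    """Gene -> functional-category map with an annotation universe."""

    categories: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.categories.values()) if self.categories else set()
        for name, genes in self.categories.items():
            if not genes:
                raise ValidationError(f"empty category {name!r}")
            if not genes <= self.universe:
                raise ValidationError(f"category {name!r} has genes outside the universe")

    def restrict(self, genes: Iterable[str]) -> "AnnotationCatalog":
        """Intersect the catalog with an external gene universe."""
        keep = self.universe & set(genes)
        cats = {n: g & keep for n, g in self.categories.items()}
        cats = {n: g for n, g in cats.items() if g}
        return AnnotationCatalog(
            categories=cats,
            descriptions={n: self.descriptions.get(n, "") for n in cats},
            universe=keep,
        )


def read_annotations(
    path: str | Path, format: str = "gmt", universe: Iterable[str] | None = None
) -> AnnotationCatalog:
    """Read a GMT (Broad dialect) or two-column (gene, category) TSV file."""
    path = Path(path)
    categories: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"empty annotation file {path}")
    if format == "gmt":
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line with fewer than 3 fields: {ln!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in categories:
                warnings.warn(f"duplicate category {name!r}; merging")
                categories[name] |= set(genes)
            else:
                categories[name] = set(genes)
                descriptions[name] = desc
    elif format == "tsv2col":
        start = 1 if lines[0].lower().startswith(("gene\t", "gene_id\t")) else 0
        for ln in lines[start:]:
            parts = ln.split("\t")
            if len(parts) != 2:
                raise FormatError(f"expected 2 tab-separated fields: {ln!r}")
            gene, cat = parts
            categories.setdefault(cat, set()).add(gene)
            descriptions.setdefault(cat, "")
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    universe_set = set(universe) if universe is not None else set()
    return AnnotationCatalog(categories=categories, descriptions=descriptions, universe=universe_set)


def write_gmt(catalog: AnnotationCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(catalog.categories):
            desc = catalog.descriptions.get(name, "")
            genes = "\t".join(sorted(catalog.categories[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------
# edge tables
# ---------------------------------------------------------------------

EDGE_COLUMNS = ["source", "target", "weight", "edge_type", "directed"]


def make_edge_table(rows: Iterable[tuple]) -> pd.DataFrame:
    """Build a validated edge table from (source, target, weight, type, directed) rows."""
    table = pd.DataFrame(list(rows), columns=EDGE_COLUMNS)
    return _validate_edges(table)


def _validate_edges(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["source"] = table["source"].astype(str)
    table["target"] = table["target"].astype(str)
    table["weight"] = table["weight"].astype(float)
    if (table["weight"] < 0).any():
        bad = table.loc[table["weight"] < 0].iloc[0]
        raise ValidationError(f"negative edge weight on {bad['source']}->{bad['target']}")
    directed = table["directed"]
    if not set(pd.unique(directed.astype(str))) <= {"0", "1", "True", "False"}:
        raise FormatError(f"malformed 'directed' flag values: {sorted(set(directed))}")
    table["directed"] = directed.astype(str).map({"0": False, "1": True, "False": False, "True": True})
    loops = table["source"] == table["target"]
    if loops.any():
        warnings.warn(f"dropping {int(loops.sum())} self-loop edge rows")
        table = table.loc[~loops]
    return table.reset_index(drop=True)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns source, target, weight, edge_type, directed.

    ``weight`` defaults to 1.0 and ``edge_type`` to ``"link"`` when the
    column is absent; self-loop rows are dropped with a warning.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"source", "target"} <= set(table.columns):
        raise FormatError("edge table needs at least columns 'source' and 'target'")
    if "weight" not in table.columns:
        table["weight"] = 1.0
    if "edge_type" not in table.columns:
        table["edge_type"] = "link"
    if "directed" not in table.columns:
        table["directed"] = "1"
    try:
        table["weight"] = table["weight"].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric weight in {path}: {exc}") from exc
    return _validate_edges(table[EDGE_COLUMNS])


def write_edge_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["directed"] = out["directed"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_pajek(nodes: list[str], arcs: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    """Write a Pajek .net file (``*Vertices`` then ``*Arcs``)."""
    index = {n: i + 1 for i, n in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            fh.write(f'{index[n]} "{n}"\n')
        fh.write("*Arcs\n")
        for s, t, w in arcs:
            fh.write(f"{index[s]} {index[t]} {w:.10g}\n")
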