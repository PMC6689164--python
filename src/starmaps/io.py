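"""Readers, writers and bundled example data.

Count tables are UTF-8 tab-separated text: first header cell ``taxon_id``,
remaining header cells sample identifiers, integer cells. Metadata is a
two-column TSV (sample_id, group); taxonomy a two-column TSV
(taxon_id, semicolon-delimited lineage). Results serialize to JSON (lossless,
schema-versioned) and to a flat TSV summary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .compositions import CountTable
from .core import StarmapsResult
from .simulate import PerformanceSummary, SimulationSpec, make_template, simulate_pair

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_result",
    "read_result",
    "make_fixtures",
    "FIXTURE_SEED",
]

RESULT_TSV_COLUMNS = [
    "p1", "p2_sample", "p2_taxon", "p2", "cos_theta", "p3", "omnibus_p", "n_axes", "seed",
]


def _check_duplicates(names: list[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for n in names:
        if n in seen:
            dups.append(n)
        seen.add(n)
    if dups:
        raise ValueError(f"duplicate {what}(s): {sorted(set(dups))}")


def read_metadata(path: str | Path) -> dict[str, str]:
    """sample_id -> group from a two-column TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" not in cols or "group" not in cols:
        raise ValueError(f"{path}: metadata needs 'sample_id' and 'group' columns")
    df.columns = cols
    _check_duplicates(list(df["sample_id"]), "sample_id")
    if df["group"].isna().any():
        bad = list(df.loc[df["group"].isna(), "sample_id"])
        raise ValueError(f"{path}: samples missing group labels: {bad}")
    return dict(zip(df["sample_id"], df["group"]))


def write_metadata(groups: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


def read_count_table(path: str | Path, meta_path: str | Path, level: str | None = None) -> CountTable:
    """Read a taxon-by-sample TSV and join group labels from the metadata TSV.

    Rows with zero total are retained (taxon matching may still use them).
    Non-integer cells, duplicate identifiers, and samples without a group
    label are errors.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "taxon_id":
        raise ValueError(f"{path}: first header cell must be 'taxon_id'")
    sample_ids = header[1:]
    _check_duplicates(sample_ids, "sample column")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    _check_duplicates([str(t) for t in df.index], "taxon_id")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.floor(values)):
        raise ValueError(f"{path}: non-integer cells present")
    groups = read_metadata(meta_path)
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValueError(f"{path}: samples missing group labels: {missing}")
    return CountTable(
        taxon_ids=[str(t) for t in df.index],
        sample_ids=list(sample_ids),
        counts=values.astype(np.int64),
        groups={s: groups[s] for s in sample_ids},
        level=level,
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\t" + "\t".join(table.sample_ids) + "\n")
        for i, tid in enumerate(table.taxon_ids):
            fh.write(tid + "\t" + "\t".join(str(int(c)) for c in table.counts[i]) + "\n")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """taxon_id -> lineage string from a two-column TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: taxonomy needs two columns")
    _check_duplicates(list(df.iloc[:, 0]), "taxon_id")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_result(result: StarmapsResult | PerformanceSummary, path: str | Path, format: str = "json") -> None:
    """Serialize a result losslessly (json) or as a flat summary row (tsv)."""
    path = Path(path)
    if format == "json":
        payload = result.to_dict()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=_to_jsonable)
            fh.write("\n")
    elif format == "tsv":
        if isinstance(result, StarmapsResult):
            row = result.flat_dict()
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("\t".join(RESULT_TSV_COLUMNS) + "\n")
                fh.write("\t".join(repr(row[c]) if isinstance(row[c], float) else str(row[c]) for c in RESULT_TSV_COLUMNS) + "\n")
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("threshold\tsensitivity\tspecificity\n")
                for t, se, sp in zip(result.thresholds, result.sensitivity, result.specificity):
                    fh.write(f"{t}\t{se}\t{sp}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_result(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


FIXTURE_SEED = 424242  # fixed seed of the bundled example pair


def make_fixtures(seed: int = FIXTURE_SEED) -> SimulationSpec:
    """Deterministic tiny example pair: 30 taxa, 2 groups x 4 samples each,
    known similar truth with a strong (log2FC = 4) effect."""
    template = make_template(n_species=30, seed=seed)
    return SimulationSpec(
        n_per_group=4, log2fc_mean=4.0, log2fc_sd=0.0, overlap=1.0,
        prop_da=0.10, n_pairs=1, template=template, seed=seed,
    )


def fixture_pair(seed: int = FIXTURE_SEED):
    """The bundled example pair itself (regenerated, byte-stable per seed)."""
    return simulate_pair(make_fixtures(seed), "similar", seed=seed)
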