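"""TSV readers/writers and run provenance.

The canonical on-disk formats are plain TSVs: count tables with samples
as rows (first column the sample id, header row of SV ids), a qPCR table
of (sample id, concentration) pairs, and a metadata table keyed by
sample id.  Writers are deterministic (fixed column order) and every run
emits a JSON summary carrying the resolved configuration, seed, package
versions, input checksums and a manifest of files written, so that two
runs with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_count_table",
    "read_qpcr_table",
    "read_metadata",
    "read_matrix",
    "sha256_file",
    "write_results",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate sample id(s) in {path}: {dups}")
    return df


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read an SV count table, validating every cell as a nonnegative integer.

    Malformed cells are reported with their (sample, SV) coordinates.
    """
    df = _read_tsv(path)
    try:  # fast path: every cell already a valid integer literal
        out = df.astype(np.int64)
        if (out.to_numpy() < 0).any():
            raise ValueError
        return out
    except (TypeError, ValueError):
        pass
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    bad: list[str] = []
    for col in df.columns:
        for row, cell in df[col].items():
            try:
                value = int(cell)
                if value < 0:
                    raise ValueError
            except (TypeError, ValueError):
                bad.append(f"(sample={row!r}, sv={col!r}, value={cell!r})")
                continue
            out.loc[row, col] = value
    if bad:
        raise ValueError("non-integer count cell(s): " + ", ".join(bad[:10]))
    return out.astype(int)


def read_qpcr_table(path: str | Path) -> pd.Series:
    """Read a (sample id, total 16S concentration) table as a Series."""
    df = _read_tsv(path)
    if df.shape[1] < 1:
        raise ValueError(f"qPCR table {path} needs a concentration column")
    s = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if s.isna().any():
        bad = list(s.index[s.isna()])
        raise ValueError(f"non-numeric qPCR value(s) for sample(s): {bad}")
    return s.rename("qpcr")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table (time/replicate/condition/donor)."""
    df = _read_tsv(path)
    if "time" in df.columns:
        df["time"] = pd.to_numeric(df["time"])
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], downcast="integer")
    return df


def read_matrix(path: str | Path, boolean: bool = False) -> pd.DataFrame:
    """Read a generic numeric (or 0/1 boolean) matrix TSV."""
    df = _read_tsv(path).apply(pd.to_numeric)
    return df.astype(bool) if boolean else df


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame | pd.Series],
    summary: dict,
    output_dir: str | Path,
    force: bool = False,
) -> list[str]:
    """Write result tables plus a run-summary JSON; return the manifest.

    Each table lands at ``<name>.tsv`` with deterministic column order;
    existing files are refused unless ``force``.  The summary gains
    package/library versions and the manifest before being written to
    ``run_summary.json``.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name, table in tables.items():
        dest = outdir / f"{name}.tsv"
        if dest.exists() and not force:
            raise FileExistsError(f"{dest} exists; pass force=True to overwrite")
        if isinstance(table, pd.Series):
            table = table.to_frame()
        table.to_csv(dest, sep="\t")
        manifest.append(dest.name)

    from . import __version__

    summary = dict(summary)
    summary["versions"] = {
        "dropculture": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    summary["manifest"] = sorted(manifest) + ["run_summary.json"]
    dest = outdir / "run_summary.json"
    if dest.exists() and not force:
        raise FileExistsError(f"{dest} exists; pass force=True to overwrite")
    dest.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    manifest.append(dest.name)
    return sorted(manifest)
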