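"""Plain-text simulation-directory format and reference-table I/O.

A simulation directory holds one file per taxon (rows of folded-SFS
proportions, one row per simulation) plus one file per hyperparameter,
per-taxon parameter vector and parameter summary, all row-aligned.  Numeric
formatting is fixed at 6 significant digits (stated in each header);
``provenance.json`` records the spec fingerprint, seed and row count so any
output can be re-run exactly.  Parallel shards written to separate
directories merge by row concatenation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .aggregate import asfs_matrix
from .inference import ReferenceTable
from .pipeline import (
    LABEL_COLUMNS,
    SUMMARY_COLUMNS,
    SimulationBatch,
    spec_fingerprint,
)

__all__ = [
    "write_simulation_dir",
    "read_simulation_dir",
    "merge_to_reference_table",
    "write_reference_table",
    "read_reference_table",
]

_FMT = "%.6g"


def _write_matrix(path: Path, mat: np.ndarray, header: str) -> None:
    np.savetxt(path, np.atleast_2d(mat), fmt=_FMT, header=header)


def write_simulation_dir(
    directory: str | Path,
    batch: SimulationBatch,
    spec,
    seed: int,
    append: bool = False,
) -> list[Path]:
    """Write a simulation batch as the plain-text directory layout.

    Emits ``taxon_XX.tsv`` per taxon plus one file per hyperparameter
    (``Psi``, ``psi``, ``sigma``, ``zeta_T``), per-taxon parameter vector
    (``tau``, ``epsilon``, ``N``) and parameter summary (``omega_tau``,
    ``e_tau``).  With ``append`` rows are added to existing files (the row
    counts must already agree; a partial previous write is detected).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_sims, n_taxa, _ = batch.taxon_data.shape
    header = (
        f"6 significant digits; mode={batch.mode} "
        f"n_samples={batch.n_samples} n_genealogies={batch.n_genealogies}"
    )

    written = []
    mode = "a" if append else "w"
    matrices: dict[str, np.ndarray] = {}
    for t in range(n_taxa):
        matrices[f"taxon_{t + 1:02d}.tsv"] = batch.taxon_data[:, t, :]
    for k in LABEL_COLUMNS:
        matrices[f"{k}.tsv"] = batch.labels[k][:, None]
    for k in SUMMARY_COLUMNS:
        matrices[f"{k}.tsv"] = batch.param_summaries[k][:, None]
    for k in ("tau", "epsilon", "N"):
        matrices[f"{k}.tsv"] = batch.taxon_params[k]

    if append:
        counts = {
            name: _count_rows(directory / name) for name in matrices if (directory / name).exists()
        }
        if len(set(counts.values())) > 1:
            raise ValueError(
                f"partial previous write detected in {directory}: row counts {counts}"
            )
    for name, mat in matrices.items():
        path = directory / name
        with path.open(mode) as fh:
            if mode == "w":
                fh.write(f"# {header}\n")
            np.savetxt(fh, np.atleast_2d(mat), fmt=_FMT)
        written.append(path)

    prov_path = directory / "provenance.json"
    prev_rows = 0
    if append and prov_path.exists():
        prev_rows = json.loads(prov_path.read_text()).get("n_sims", 0)
    prov_path.write_text(
        json.dumps(
            {
                "spec": spec_fingerprint(spec),
                "seed": seed,
                "n_sims": prev_rows + n_sims,
                "n_taxa": n_taxa,
                "n_samples": batch.n_samples,
                "n_genealogies": batch.n_genealogies,
                "format": "6 significant digits",
            },
            indent=1,
        )
    )
    return written


def _count_rows(path: Path) -> int:
    with path.open() as fh:
        return sum(1 for ln in fh if ln.strip() and not ln.startswith("#"))


def _read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def read_simulation_dir(directory: str | Path) -> dict[str, np.ndarray]:
    """Read one simulation directory back into arrays.

    Returns a dict with ``sfs`` of shape ``(n_sims, n_taxa, n_classes)`` and
    one entry per label / parameter file.  Raises on row-count mismatches.
    """
    directory = Path(directory)
    taxa = sorted(directory.glob("taxon_*.tsv"))
    if not taxa:
        raise FileNotFoundError(f"no taxon files in {directory}")
    sfs = np.stack([_read_matrix(p) for p in taxa], axis=1)
    out: dict[str, np.ndarray] = {"sfs": sfs}
    for name in LABEL_COLUMNS + SUMMARY_COLUMNS:
        p = directory / f"{name}.tsv"
        if p.exists():
            out[name] = _read_matrix(p).ravel()
    for name in ("tau", "epsilon", "N"):
        p = directory / f"{name}.tsv"
        if p.exists():
            out[name] = _read_matrix(p)
    rows = {k: v.shape[0] for k, v in out.items()}
    if len(set(rows.values())) > 1:
        raise ValueError(f"row-count mismatch across files in {directory}: {rows}")
    return out


def merge_to_reference_table(
    directories: list[str | Path],
    convert_psi: bool = False,
    n_taxa: int | None = None,
    mode: str = "asfs",
) -> ReferenceTable:
    """Merge one or more simulation directories (e.g. parallel shards) into a
    reference table aligned with the label rows: aSFS summaries in genomic
    mode, the 16 moment statistics in single-locus (``"mito"``) mode."""
    parts = [read_simulation_dir(d) for d in directories]
    shapes = {p["sfs"].shape[1:] for p in parts}
    if len(shapes) != 1:
        raise ValueError(f"directories are not schema-compatible: {shapes}")
    sfs = np.concatenate([p["sfs"] for p in parts])
    labels = {}
    for name in LABEL_COLUMNS:
        if all(name in p for p in parts):
            labels[name] = np.concatenate([p[name] for p in parts])
    summaries = {}
    for name in SUMMARY_COLUMNS:
        if all(name in p for p in parts):
            summaries[name] = np.concatenate([p[name] for p in parts])
    if convert_psi:
        from .pipeline import psi_to_capital

        n = n_taxa if n_taxa is not None else sfs.shape[1]
        labels["Psi"] = psi_to_capital(labels["psi"], n).astype(float)
    if mode == "mito":
        from .aggregate import mito_moments_matrix

        summary_matrix = mito_moments_matrix(sfs)
    else:
        summary_matrix = asfs_matrix(sfs)
    return ReferenceTable(
        summaries=summary_matrix,
        labels=labels,
        param_summaries=summaries,
        provenance={"sources": [str(d) for d in directories]},
    )


def write_reference_table(table: ReferenceTable, path: str | Path) -> None:
    """Write a reference table as one text matrix: label and parameter-summary
    columns first, then the summary-statistic columns."""
    path = Path(path)
    names = list(table.labels) + list(table.param_summaries)
    cols = [table.column(n)[:, None] for n in names]
    mat = np.hstack(cols + [table.summaries])
    header = "columns: " + " ".join(names) + f" + {table.n_stats} summary stats; 6 significant digits"
    np.savetxt(path, mat, fmt=_FMT, header=header)


def read_reference_table(path: str | Path) -> ReferenceTable:
    """Read a reference table written by :func:`write_reference_table`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().lstrip("# ").strip()
    if not header.startswith("columns:"):
        raise ValueError(f"{path}: missing column header")
    names = header.split("columns:")[1].split("+")[0].split()
    mat = np.atleast_2d(np.loadtxt(path))
    labels = {}
    summaries = {}
    for j, name in enumerate(names):
        col = mat[:, j]
        if name in SUMMARY_COLUMNS:
            summaries[name] = col
        else:
            labels[name] = col
    return ReferenceTable(
        summaries=mat[:, len(names) :],
        labels=labels,
        param_summaries=summaries,
        provenance={"source": str(path)},
    )
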