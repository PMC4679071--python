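"""Readers and writers for the plain-text formats used by the CLI.

Expression matrices are stored samples-in-rows: the header row holds gene
ids and the first column holds sample ids. MatrixMarket files carry their
identifiers in ``.rows`` / ``.cols`` sidecar files. Gene lists are one id
per line; replicate designs are two-column TSV (sample_id, group_id).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import ControlGeneSet, ExpressionMatrix, ReplicateDesign
from .simulate import SimulatedDataset, SimulationConfig

_SEPS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass fmt explicitly")


def _read_id_file(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing {what} sidecar file: {path}")
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not ids:
        raise ValueError(f"{what} sidecar file {path} is empty")
    return ids


def read_expression(
    path: str | Path, fmt: str | None = None, transpose: bool = False
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV (ids embedded) or MTX (sidecars)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt in _SEPS:
        # check header duplicates before pandas mangles them to id.1, id.2, ...
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(_SEPS[fmt])[1:]
        dups = sorted({g for g in header if header.count(g) > 1})
        if dups:
            raise ValueError(f"duplicated gene id(s) in {path}: {dups[:5]}")
        try:
            df = pd.read_csv(path, sep=_SEPS[fmt], index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed {fmt.upper()} file {path}: {exc}") from exc
        dups = df.index[df.index.duplicated()].unique().tolist()
        if dups:
            raise ValueError(f"duplicated sample id(s) in {path}: {dups[:5]}")
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        if len(bad):
            raise ValueError(
                f"non-numeric cells in {path}, column(s): {list(bad[:5])}"
            )
        values = df.to_numpy(dtype=float)
        sample_ids = [str(s) for s in df.index]
        gene_ids = [str(g) for g in df.columns]
    elif fmt == "mtx":
        from scipy.io import mmread

        mat = mmread(path)
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        sample_ids = _read_id_file(path.with_suffix(".rows"), "row-id")
        gene_ids = _read_id_file(path.with_suffix(".cols"), "column-id")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        values = values.T
        sample_ids, gene_ids = gene_ids, sample_ids
    return ExpressionMatrix(values, sample_ids, gene_ids)


def write_expression(matrix: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.gene_ids)
    if fmt in _SEPS:
        df.index.name = "sample_id"
        df.to_csv(path, sep=_SEPS[fmt], float_format="%.12g")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(matrix.values))
        path.with_suffix(".rows").write_text("\n".join(matrix.sample_ids) + "\n")
        path.with_suffix(".cols").write_text("\n".join(matrix.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_gene_list(path: str | Path, matrix: ExpressionMatrix | None = None) -> ControlGeneSet:
    """Read a one-id-per-line gene list; optionally validate against a matrix."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not ids:
        raise ValueError(f"gene list {path} is empty")
    genes = ControlGeneSet(ids)
    if matrix is not None:
        unknown = [g for g in genes.gene_ids if g not in set(matrix.gene_ids)]
        if unknown:
            raise ValueError(f"gene list {path} contains unknown ids: {unknown[:5]}")
    return genes


def write_gene_list(genes: ControlGeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(genes.gene_ids) + "\n")


def read_replicate_design(path: str | Path, matrix: ExpressionMatrix | None = None) -> ReplicateDesign:
    """Read a two-column TSV mapping sample_id -> replicate group_id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group_id"], dtype=str)
    if df.empty:
        raise ValueError(f"replicate design {path} is empty")
    if df.iloc[0].tolist() == ["sample_id", "group_id"]:
        df = df.iloc[1:]
    if df["sample_id"].isna().any() or df["group_id"].isna().any():
        raise ValueError(f"replicate design {path} has missing fields")
    groups: dict[str, list[str]] = {}
    for sid, gid in zip(df["sample_id"], df["group_id"]):
        groups.setdefault(gid, []).append(sid)
    design = ReplicateDesign(groups)
    if matrix is not None:
        unknown = [s for s in design.sample_ids if s not in set(matrix.sample_ids)]
        if unknown:
            raise ValueError(f"replicate design {path} names unknown samples: {unknown[:5]}")
    return design


def write_replicate_design(design: ReplicateDesign, path: str | Path) -> None:
    lines = ["sample_id\tgroup_id"]
    for gid, members in design.groups.items():
        lines.extend(f"{sid}\t{gid}" for sid in members)
    Path(path).write_text("\n".join(lines) + "\n")


def _write_loadings(a: np.ndarray, ids: list[str], path: Path, prefix: str) -> None:
    pd.DataFrame(a, index=[f"{prefix}{i + 1}" for i in range(a.shape[0])], columns=ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write a simulated dataset (data, metadata and ground truth) as TSV."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(ds.Y, outdir / "Y.tsv")
    write_gene_list(ds.control_genes, outdir / "controls.txt")
    write_replicate_design(ds.replicate_design, outdir / "replicates.tsv")
    sids, gids = ds.Y.sample_ids, ds.Y.gene_ids
    pd.DataFrame(ds.X, index=sids, columns=["group", "survival"]).to_csv(
        outdir / "X.tsv", sep="\t", float_format="%.12g"
    )
    pd.DataFrame(ds.W, index=sids, columns=["platform", "quality"]).to_csv(
        outdir / "W.tsv", sep="\t", float_format="%.12g"
    )
    _write_loadings(ds.beta, gids, outdir / "beta.tsv", "beta_")
    _write_loadings(ds.alpha, gids, outdir / "alpha.tsv", "alpha_")
    write_expression(ds.Y.with_values(ds.eps), outdir / "eps.tsv")
    pd.Series(ds.batch, index=sids, name="batch").to_csv(outdir / "batch.tsv", sep="\t")
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(ds.config).items()}
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def read_dataset(outdir: str | Path) -> SimulatedDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    import yaml

    outdir = Path(outdir)
    raw_cfg = yaml.safe_load((outdir / "config.yaml").read_text())
    if isinstance(raw_cfg.get("mixing"), list):
        raw_cfg["mixing"] = tuple(raw_cfg["mixing"])
    cfg = SimulationConfig(**raw_cfg)
    y = read_expression(outdir / "Y.tsv")
    x = pd.read_csv(outdir / "X.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    w = pd.read_csv(outdir / "W.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    beta = pd.read_csv(outdir / "beta.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    alpha = pd.read_csv(outdir / "alpha.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    eps = read_expression(outdir / "eps.tsv").values
    controls = read_gene_list(outdir / "controls.txt", y)
    control_mask = np.array([g in set(controls.gene_ids) for g in y.gene_ids])
    design = read_replicate_design(outdir / "replicates.tsv", y)
    batch = pd.read_csv(outdir / "batch.tsv", sep="\t", index_col=0)["batch"].to_numpy()
    return SimulatedDataset(
        Y=y, X=x, beta=beta, W=w, alpha=alpha, eps=eps,
        control_mask=control_mask, replicate_design=design, batch=batch, config=cfg,
    )
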