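"""Readers and writers for the plain-text interchange formats.

All numeric round-trips preserve 12 significant digits.  Formats:

* series: TSV, header ``node\\t<t0>\\t<t1>...``, one row per node.
* correlation matrix: square CSV with node labels as header row and column.
* graph: two-column whitespace-separated edge list of 0-based node ids, plus
  an optional sidecar label table (TSV: id, label[, group]).
* disc: ``#``-prefixed header metadata (beta, mu, r_hat, loglik) followed by
  CSV rows (node id, label, kappa, r, theta).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .s1h2 import HyperbolicDisc
from .types import BinaryGraph, CorrelationMatrix, SeriesMatrix

__all__ = [
    "read_series", "write_series",
    "read_matrix", "write_matrix",
    "read_edgelist", "write_edgelist",
    "read_labels", "write_labels",
    "read_disc", "write_disc",
    "read_grouping",
    "read_ground_truth", "write_ground_truth",
    "read_distance_matrix", "write_distance_matrix",
    "read_cohort", "write_cohort",
]

_FMT = "{:.12g}"


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _fmt(x: float) -> str:
    return _FMT.format(float(x))


def write_series(ts: SeriesMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        header = ["node"] + [f"t{k}" for k in range(ts.n_timepoints)]
        fh.write("\t".join(header) + "\n")
        for label, row in zip(ts.node_labels, ts.values):
            fh.write("\t".join([label] + [_fmt(v) for v in row]) + "\n")


def read_series(path: str | Path) -> SeriesMatrix:
    path = Path(path)
    labels: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if lineno == 1:
                if parts[0] != "node":
                    raise FormatError(f"{path}:1: expected header starting with 'node'")
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: need a label and >= 3 timepoints")
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if len({len(r) for r in rows}) > 1:
        raise FormatError(f"{path}: ragged rows (unequal timepoint counts)")
    return SeriesMatrix(values=np.array(rows), node_labels=labels)


def write_matrix(c: CorrelationMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + list(c.node_labels))
        for label, row in zip(c.node_labels, c.rho):
            writer.writerow([label] + [_fmt(v) for v in row])


def read_matrix(path: str | Path) -> CorrelationMatrix:
    path = Path(path)
    with path.open() as fh:
        reader = list(csv.reader(fh))
    if not reader:
        raise FormatError(f"{path}:1: empty matrix file")
    labels = reader[0][1:]
    n = len(labels)
    rho = np.empty((n, n))
    for k, row in enumerate(reader[1:], start=2):
        if len(row) != n + 1:
            raise FormatError(f"{path}:{k}: expected {n + 1} columns, got {len(row)}")
        try:
            rho[k - 2] = [float(v) for v in row[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{k}: non-numeric value ({exc})") from None
    if len(reader) - 1 != n:
        raise FormatError(f"{path}: matrix is not square")
    if not np.allclose(rho, rho.T, atol=1e-9):
        raise FormatError(f"{path}: matrix is not symmetric")
    return CorrelationMatrix(rho=(rho + rho.T) / 2.0, node_labels=labels)


def write_edgelist(
    g: BinaryGraph, path: str | Path, labels_path: str | Path | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for i, j in g.edge_list():
            fh.write(f"{i} {j}\n")
    if labels_path is not None:
        write_labels(list(g.node_labels), labels_path)


def read_edgelist(
    path: str | Path,
    labels_path: str | Path | None = None,
    n_nodes: int | None = None,
) -> BinaryGraph:
    path = Path(path)
    edges: list[tuple[int, int]] = []
    max_id = -1
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two node ids")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer node id") from None
            if i == j:
                raise FormatError(f"{path}:{lineno}: self-loop on node {i}")
            if i < 0 or j < 0:
                raise FormatError(f"{path}:{lineno}: negative node id")
            edges.append((i, j))
            max_id = max(max_id, i, j)
    labels = read_labels(labels_path) if labels_path else []
    n = n_nodes or (len(labels) if labels else max_id + 1)
    if max_id >= n:
        raise FormatError(f"{path}: node id {max_id} exceeds declared node count {n}")
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return BinaryGraph(adj=adj, node_labels=labels)


def write_labels(labels: list[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("id\tlabel\n")
        for k, lab in enumerate(labels):
            fh.write(f"{k}\t{lab}\n")


def read_labels(path: str | Path) -> list[str]:
    path = Path(path)
    out: dict[int, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and parts[0] == "id":
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'id<TAB>label'")
            out[int(parts[0])] = parts[1]
    return [out[k] for k in sorted(out)]


def write_disc(disc: HyperbolicDisc, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# beta={_fmt(disc.beta)}\n")
        fh.write(f"# mu={_fmt(disc.mu)}\n")
        fh.write(f"# r_hat={_fmt(disc.r_hat)}\n")
        fh.write(f"# loglik={_fmt(disc.loglik) if np.isfinite(disc.loglik) else 'nan'}\n")
        writer = csv.writer(fh)
        writer.writerow(["node_id", "label", "kappa", "r", "theta"])
        for k in range(disc.n_nodes):
            writer.writerow(
                [k, disc.node_labels[k], _fmt(disc.kappa[k]), _fmt(disc.r[k]),
                 _fmt(disc.theta[k])]
            )


def read_disc(path: str | Path) -> HyperbolicDisc:
    path = Path(path)
    meta: dict[str, float] = {}
    rows: list[list[str]] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = float(val)
            else:
                rows.append(line.rstrip("\n").split(","))
    for key in ("beta", "mu"):
        if key not in meta:
            raise FormatError(f"{path}: missing required '# {key}=' header")
    if not rows or rows[0][:2] != ["node_id", "label"]:
        raise FormatError(f"{path}: missing column header row")
    body = rows[1:]
    labels = [r[1] for r in body]
    kappa = np.array([float(r[2]) for r in body])
    r = np.array([float(r[3]) for r in body])
    theta = np.array([float(r[4]) for r in body])
    return HyperbolicDisc(
        r=r, theta=theta, kappa=kappa, beta=meta["beta"], mu=meta["mu"],
        node_labels=labels, loglik=meta.get("loglik", float("nan")),
    )


def write_ground_truth(gt, path: str | Path) -> None:
    """CSV (id, kappa, theta) plus beta/mu header metadata."""
    with Path(path).open("w", newline="") as fh:
        fh.write(f"# beta={_fmt(gt.beta)}\n")
        fh.write(f"# mu={_fmt(gt.mu)}\n")
        writer = csv.writer(fh)
        writer.writerow(["id", "kappa", "theta"])
        for k in range(gt.n_nodes):
            writer.writerow([k, _fmt(gt.kappa[k]), _fmt(gt.theta[k])])


def read_ground_truth(path: str | Path):
    from .synthcohort import GroundTruthS1

    path = Path(path)
    meta: dict[str, float] = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = float(val)
            else:
                rows.append(line.rstrip("\n").split(","))
    for key in ("beta", "mu"):
        if key not in meta:
            raise FormatError(f"{path}: missing required '# {key}=' header")
    body = rows[1:]
    return GroundTruthS1(
        kappa=np.array([float(r[1]) for r in body]),
        theta=np.array([float(r[2]) for r in body]),
        beta=meta["beta"],
        mu=meta["mu"],
    )


def write_distance_matrix(d: np.ndarray, path: str | Path,
                          labels: list[str] | None = None) -> None:
    """Square CSV of symmetric non-negative distances, zero diagonal."""
    d = np.asarray(d, dtype=float)
    labels = labels or [str(i) for i in range(d.shape[0])]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + labels)
        for lab, row in zip(labels, d):
            writer.writerow([lab] + [_fmt(v) for v in row])


def read_distance_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    with path.open() as fh:
        reader = list(csv.reader(fh))
    if not reader:
        raise FormatError(f"{path}:1: empty matrix file")
    labels = reader[0][1:]
    n = len(labels)
    d = np.empty((n, n))
    for k, row in enumerate(reader[1:], start=2):
        if len(row) != n + 1:
            raise FormatError(f"{path}:{k}: expected {n + 1} columns")
        d[k - 2] = [float(v) for v in row[1:]]
    if len(reader) - 1 != n:
        raise FormatError(f"{path}: matrix is not square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise FormatError(f"{path}: matrix is not symmetric")
    return (d + d.T) / 2.0, labels


def write_cohort(cohort, directory: str | Path) -> Path:
    """Cohort as a directory: manifest YAML, ground truth, per-subject edges."""
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ground_truth(cohort.ground_truth, directory / "ground_truth.csv")
    names = []
    for k, g in enumerate(cohort.subjects):
        name = f"subject_{k:03d}.edgelist"
        write_edgelist(g, directory / name)
        names.append(name)
    manifest = {
        "n_nodes": cohort.subjects[0].n_nodes,
        "subjects": names,
        "ground_truth": "ground_truth.csv",
        "perturbation_log": [
            {"subject": s, "pair": [int(i), int(j)], "mode": mode}
            for s, (i, j), mode in cohort.perturbation_log
        ],
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return directory / "manifest.yaml"


def read_cohort(manifest_path: str | Path):
    import yaml

    from .synthcohort import SyntheticCohort

    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    gt = read_ground_truth(base / manifest["ground_truth"])
    n = int(manifest["n_nodes"])
    subjects = [read_edgelist(base / name, n_nodes=n)
                for name in manifest["subjects"]]
    log = [(e["subject"], (e["pair"][0], e["pair"][1]), e["mode"])
           for e in manifest.get("perturbation_log", [])]
    return SyntheticCohort(subjects=subjects, ground_truth=gt,
                           perturbation_log=log)


def read_grouping(path: str | Path) -> dict[int, str]:
    """TSV (node id, region label) -> mapping used by region aggregation."""
    path = Path(path)
    out: dict[int, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and not parts[0].lstrip("-").isdigit():
                continue  # header
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'id<TAB>region'")
            out[int(parts[0])] = parts[1]
    return out
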