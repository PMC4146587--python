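"""Tabular text formats for expression data, prior weights and networks.

Expression uses a long/tidy TSV (gene, time, replicate, value) because
replicate counts differ across time points and observed times are
non-uniform, so a rectangular matrix cannot represent the data.  Exogenous
biomolecule series ride in the same file flagged by ``kind=exogenous``.
Times are real-valued hours; grid times are always derived, never stored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model_core import PenaltyConfig, TimeCourseDataset
from .structure_search import Edge, NetworkEstimate

__all__ = [
    "read_expression",
    "write_expression",
    "read_priors",
    "write_network",
    "read_network_edges",
    "write_sif",
    "write_scan_table",
    "RunConfig",
]


def read_expression(path) -> TimeCourseDataset:
    """Read a tidy expression TSV into a dataset.

    Columns: gene, time, replicate, value, and optional kind
    (``gene`` | ``exogenous``).  Exogenous rows define the concentration
    series (their replicate column is ignored).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "time", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric value at line {bad.index[0] + 2}")
    df["value"] = df["value"].astype(float)
    if "kind" not in df.columns:
        df["kind"] = "gene"
    df["kind"] = df["kind"].fillna("gene")

    gene_rows = df[df["kind"] == "gene"]
    dup = gene_rows.duplicated(subset=["gene", "time", "replicate"])
    if dup.any():
        rec = gene_rows[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record (gene={rec['gene']}, time={rec['time']}, "
            f"replicate={rec['replicate']})")
    genes = sorted(gene_rows["gene"].unique())
    gi = {g: i for i, g in enumerate(genes)}
    y: dict[float, list[np.ndarray]] = {}
    for t, sub in gene_rows.groupby("time"):
        reps = sorted(sub["replicate"].unique())
        vecs = []
        for r in reps:
            s = sub[sub["replicate"] == r]
            if len(s) != len(genes):
                raise ValueError(
                    f"{path}: replicate {r} at time {t} has {len(s)} genes, expected {len(genes)}")
            v = np.empty(len(genes))
            v[[gi[g] for g in s["gene"]]] = s["value"].to_numpy()
            vecs.append(v)
        y[float(t)] = vecs

    exo_rows = df[df["kind"] == "exogenous"]
    u_times = u_values = None
    if len(exo_rows):
        species = sorted(exo_rows["gene"].unique())
        times = np.asarray(sorted(exo_rows["time"].unique()), dtype=float)
        u_values = np.zeros((times.size, len(species)))
        ti = {t: i for i, t in enumerate(times)}
        for m, sp in enumerate(species):
            s = exo_rows[exo_rows["gene"] == sp]
            for _, row in s.iterrows():
                u_values[ti[float(row["time"])], m] = row["value"]
        u_times = times
    return TimeCourseDataset(genes=genes, y=y, u_times=u_times, u_values=u_values)


def write_expression(data: TimeCourseDataset, path) -> None:
    rows = []
    for t in sorted(data.y):
        for r, vec in enumerate(data.y[t], start=1):
            for g, v in zip(data.genes, vec):
                rows.append((g, t, r, repr(float(v)), "gene"))
    if data.n_exo:
        for m in range(data.n_exo):
            for t, v in zip(data.u_times, data.u_values[:, m]):
                rows.append((f"exo{m}", float(t), 1, repr(float(v)), "exogenous"))
    pd.DataFrame(rows, columns=["gene", "time", "replicate", "value", "kind"]) \
        .to_csv(path, sep="\t", index=False)


def read_priors(path, genes, n_exo: int = 0) -> PenaltyConfig:
    """Read known-regulation weights (regulator, target, weight TSV).

    Listed pairs get their weight (< 1 favours selection); everything else
    keeps weight 1.  An ``exoM`` regulator name addresses exogenous input M.
    """
    pen = PenaltyConfig.default(len(genes), n_exo)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return pen
    required = {"regulator", "target", "weight"}
    if required - set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    gi = {g: i for i, g in enumerate(genes)}
    seen: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        wt = float(row["weight"])
        if not (0.0 < wt <= 1.0):
            raise ValueError(f"{path}: weight {wt} outside (0, 1]")
        key = (str(row["regulator"]), str(row["target"]))
        if key in seen and seen[key] != wt:
            raise ValueError(f"{path}: conflicting weights for pair {key}")
        seen[key] = wt
        tgt = gi[key[1]]
        if key[0].startswith("exo") and key[0] not in gi:
            pen.cB[tgt, int(key[0][3:])] = wt
        else:
            pen.cA[tgt, gi[key[0]]] = wt
    return pen


def write_network(estimate: NetworkEstimate, path) -> None:
    """Edge-list TSV plus a YAML summary block (BIC, per-row penalty levels)."""
    df = pd.DataFrame(
        [(e.regulator, e.target, e.sign, repr(e.coef), int(e.is_exogenous),
          int(e.weight < 1.0)) for e in estimate.edges],
        columns=["regulator", "target", "sign", "coefficient", "is_exogenous",
                 "was_weighted"])
    df.to_csv(path, sep="\t", index=False)
    summary = {
        "bic": float(estimate.bic),
        "loglik": float(estimate.loglik),
        "df": int(estimate.df),
        "n_sample": int(estimate.n_sample),
        "row_lambda": [float(x) for x in estimate.row_lambda],
        "genes": list(estimate.genes),
    }
    with open(str(path) + ".summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh)


def read_network_edges(path) -> list[Edge]:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []
    return [Edge(str(r["regulator"]), str(r["target"]), float(r["coefficient"]),
                 int(r["sign"]), bool(r["is_exogenous"]),
                 0.5 if r["was_weighted"] else 1.0)
            for _, r in df.iterrows()]


def write_sif(estimate: NetworkEstimate, path) -> None:
    """SIF export: regulator <activates|represses> target."""
    with open(path, "w") as fh:
        for e in estimate.edges:
            rel = "activates" if e.sign > 0 else "represses"
            fh.write(f"{e.regulator}\t{rel}\t{e.target}\n")


def write_scan_table(scan, path) -> None:
    rows = [(e.k, e.bic, e.spe, len([x for x in e.estimate.edges if not x.is_exogenous]))
            for e in scan.entries]
    pd.DataFrame(rows, columns=["k", "bic", "spe", "n_edges"]) \
        .to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Serializable run configuration (YAML round-trip)."""

    k: int = 1
    k_values: list[int] = field(default_factory=lambda: [1, 2, 3])
    observed_times: list[float] | None = None
    heldout_times: list[float] | None = None
    priors_file: str | None = None
    i_max: int = 3
    C_max: int = 10
    lambda_decay: float = 0.9
    em_tol: float = 1e-6
    em_max_iter: int = 500
    seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
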