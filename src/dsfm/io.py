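"""File formats: long-format count panels (CSV), adjacency edge lists,
loadings-pattern files, sampler configuration (YAML) and run manifests.

All indices in files are 0-based.  The panel CSV is long format with one row
per (unit, time, outcome) cell and columns ``unit_id, time, outcome, count,
censored, population``; the panel must be complete.  The edge list has two
integer columns, one undirected edge per line, whitespace- or
comma-separated.  The pattern file holds the 0/1 mask row by row, then
``anchor`` lines and an optional ``order`` line.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from .model import CENSOR_HI, CENSOR_LO, CountPanel, LoadingsPattern
from .prior import AdjacencyGraph
from .sampler import SamplerConfig

PANEL_COLUMNS = ["unit_id", "time", "outcome", "count", "censored", "population"]


def read_panel_csv(path) -> CountPanel:
    """Read a complete long-format panel CSV into a CountPanel.

    Unit, time and outcome axes are ordered by first appearance for string
    labels and numerically for integers.  Duplicated cells, negative counts
    or populations, and missing cells are errors; a censored row whose count
    lies outside the suppression interval triggers a warning (the value is
    ignored anyway).
    """
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} is missing columns {missing}")
    dup = df.duplicated(subset=["unit_id", "time", "outcome"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header and 0-base
        raise ValueError(f"duplicated (unit,time,outcome) cells at lines {lines}")

    def _axis(col):
        vals = df[col].unique().tolist()
        try:
            return sorted(vals, key=float)
        except (TypeError, ValueError):
            return vals

    units = _axis("unit_id")
    times = _axis("time")
    outcomes = _axis("outcome")
    I, J, K = len(units), len(times), len(outcomes)
    if len(df) != I * J * K:
        raise ValueError(
            f"incomplete panel: {len(df)} rows, expected {I * J * K} "
            f"({I} units x {J} times x {K} outcomes)")
    ui = {u: i for i, u in enumerate(units)}
    ti = {t: j for j, t in enumerate(times)}
    oi = {o: k for k, o in enumerate(outcomes)}

    counts = np.zeros((I, J, K), dtype=np.int64)
    cens = np.zeros((I, J, K), dtype=bool)
    pops = np.full((I, J), np.nan)
    cvals = df["censored"].astype(str).str.strip().str.lower()
    cflag = cvals.isin(["1", "true", "t", "yes"]).to_numpy()
    iidx = df["unit_id"].map(ui).to_numpy()
    jidx = df["time"].map(ti).to_numpy()
    kidx = df["outcome"].map(oi).to_numpy()
    raw_counts = df["count"].fillna(0).to_numpy()
    if np.any(raw_counts[~cflag] < 0):
        raise ValueError("negative count in panel file")
    pop_col = df["population"].to_numpy(dtype=float)
    if np.any(pop_col <= 0):
        raise ValueError("nonpositive population in panel file")
    counts[iidx, jidx, kidx] = raw_counts.astype(np.int64)
    cens[iidx, jidx, kidx] = cflag
    pops[iidx, jidx] = pop_col
    bad = cflag & ((raw_counts < CENSOR_LO) | (raw_counts > CENSOR_HI)) \
        & (df["count"].notna().to_numpy())
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} censored rows carry a count outside "
            f"[{CENSOR_LO},{CENSOR_HI}]; the stored value is ignored",
            stacklevel=2)
    return CountPanel(counts=counts, censored=cens, populations=pops,
                      unit_labels=units, time_labels=times,
                      outcome_labels=outcomes)


def write_panel_csv(panel: CountPanel, path) -> None:
    """Write a CountPanel as long-format CSV (inverse of read_panel_csv)."""
    rows = []
    for i, u in enumerate(panel.unit_labels):
        for j, t in enumerate(panel.time_labels):
            for k, o in enumerate(panel.outcome_labels):
                rows.append((u, t, o, int(panel.counts[i, j, k]),
                             bool(panel.censored[i, j, k]),
                             panel.populations[i, j]))
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)


def read_adjacency(path, n_units: int) -> AdjacencyGraph:
    """Read an undirected edge list (0-based integer pairs) into a graph.

    Connectivity, self-loops and index range are validated by the
    AdjacencyGraph constructor; indices must cover 0..n_units-1.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two indices")
            edges.append((int(parts[0]), int(parts[1])))
    if not edges:
        raise ValueError(f"{path}: empty edge list")
    return AdjacencyGraph(n_units=n_units, edges=np.array(edges))


def write_adjacency(graph: AdjacencyGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u} {v}\n")


def read_pattern(path) -> LoadingsPattern:
    """Read a loadings pattern file.

    Format: one line of 0/1 tokens per outcome row, then one
    ``anchor <row> <col>`` line per factor, and an optional
    ``order <i0> <i1> ...`` line.
    """
    mask_rows, anchors, order = [], [], None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if parts[0] == "anchor":
                anchors.append((int(parts[1]), int(parts[2])))
            elif parts[0] == "order":
                order = tuple(int(p) for p in parts[1:])
            else:
                mask_rows.append([int(p) for p in parts])
    mask = np.array(mask_rows, dtype=bool)
    if order is None:
        order = tuple(range(mask.shape[0]))
    return LoadingsPattern(mask=mask, anchors=tuple(anchors), outcome_order=order)


def write_pattern(pattern: LoadingsPattern, path) -> None:
    with open(path, "w") as fh:
        for row in pattern.mask.astype(int):
            fh.write(" ".join(map(str, row)) + "\n")
        for (k, j) in pattern.anchors:
            fh.write(f"anchor {k} {j}\n")
        fh.write("order " + " ".join(map(str, pattern.outcome_order)) + "\n")


def read_config(path) -> SamplerConfig:
    """Read a YAML sampler configuration.

    Keys: iterations, burn_in, thin, seed, adapt, and a proposal_sd mapping
    per block; all optional, defaulting to the production settings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "iterations" in raw:
        kwargs["n_iter"] = int(raw["iterations"])
    for key in ("burn_in", "thin", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "adapt" in raw:
        kwargs["adapt"] = bool(raw["adapt"])
    if "proposal_sd" in raw:
        kwargs["proposal_sd"] = {k: float(v)
                                 for k, v in raw["proposal_sd"].items()}
    return SamplerConfig(**kwargs)


# ---------------------------------------------------------------------------
# Draw / truth archives (runtime artifacts, NumPy .npz)
# ---------------------------------------------------------------------------


def _pattern_arrays(pattern: LoadingsPattern) -> dict:
    return {
        "pattern_mask": pattern.mask.astype(np.int8),
        "pattern_anchors": np.array(pattern.anchors, dtype=np.int64),
        "pattern_order": np.array(pattern.outcome_order, dtype=np.int64),
    }


def _pattern_from_arrays(d) -> LoadingsPattern:
    return LoadingsPattern(mask=d["pattern_mask"].astype(bool),
                           anchors=tuple(map(tuple, d["pattern_anchors"])),
                           outcome_order=tuple(d["pattern_order"]))


def save_samples(samples, path) -> None:
    """Archive retained posterior draws to a .npz file."""
    arrays = {"gamma": samples.gamma, "L": samples.L, "mu": samples.mu,
              "eta": samples.eta, "sigma2": samples.sigma2}
    for name in ("F", "F_tilde", "epsilon"):
        val = getattr(samples, name)
        if val is not None:
            arrays[name] = val
    arrays.update(_pattern_arrays(samples.pattern))
    arrays["acceptance_json"] = np.array(json.dumps(samples.acceptance))
    np.savez_compressed(path, **arrays)


def load_samples(path):
    """Load a draw archive back into a PosteriorSamples."""
    from .sampler import PosteriorSamples, SamplerConfig
    with np.load(path, allow_pickle=False) as d:
        pattern = _pattern_from_arrays(d)
        n = d["gamma"].shape[0]
        cfg = SamplerConfig(n_iter=max(n, 1), burn_in=0, thin=1)
        return PosteriorSamples(
            gamma=d["gamma"], L=d["L"], mu=d["mu"], eta=d["eta"],
            sigma2=d["sigma2"],
            F=d["F"] if "F" in d else None,
            F_tilde=d["F_tilde"] if "F_tilde" in d else None,
            epsilon=d["epsilon"] if "epsilon" in d else None,
            acceptance=json.loads(str(d["acceptance_json"])),
            pattern=pattern, config=cfg)


def save_truth(truth, path) -> None:
    """Archive a synthetic TruthBundle to a .npz file."""
    arrays = {
        "gamma": truth.gamma, "Q": truth.Q, "f": truth.factors.f,
        "f_tilde": truth.f_tilde, "mu": truth.hyper.mu,
        "eta": truth.hyper.eta, "sigma2": truth.sigma2,
        "epsilon": truth.epsilon, "rates": truth.rates,
        "censor_mask": truth.censor_mask.astype(np.int8),
    }
    if truth.L is not None:
        arrays["L"] = truth.L
    arrays.update(_pattern_arrays(truth.loadings.pattern)
                  if truth.loadings is not None else {})
    np.savez_compressed(path, **arrays)


def load_truth(path):
    """Load a truth archive back into a TruthBundle."""
    from .model import LoadingsMatrix
    from .prior import FactorField, FactorHyper
    from .synthetic import TruthBundle
    with np.load(path, allow_pickle=False) as d:
        pattern = (_pattern_from_arrays(d) if "pattern_mask" in d else None)
        gamma = d["gamma"]
        loadings = (LoadingsMatrix(values=gamma, pattern=pattern)
                    if pattern is not None else None)
        return TruthBundle(
            gamma=gamma, loadings=loadings,
            L=d["L"] if "L" in d else None, Q=d["Q"],
            factors=FactorField(f=d["f"]), f_tilde=d["f_tilde"],
            hyper=FactorHyper(mu=d["mu"], eta=d["eta"]),
            sigma2=d["sigma2"], epsilon=d["epsilon"], rates=d["rates"],
            censor_mask=d["censor_mask"].astype(bool))


@dataclass
class RunManifest:
    """Record of one model fit, sufficient to re-run it bit-identically."""

    counts_path: str
    edges_path: str
    pattern_path: str
    config: dict
    seed: int
    package_version: str
    started: str
    finished: str
    acceptance_rates: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def utcnow() -> str:
    return datetime.now(timezone.utc).isoformat()
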