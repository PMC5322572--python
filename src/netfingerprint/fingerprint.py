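"""Fingerprint orchestration: compute, rank, export, compare.

A Network Fingerprint of a query network G against an ordered reference
set P = (P_1, …, P_n) is the vector S = (s_1, …, s_n), where each s_i is
the z-standardized similarity between G and P_i.  The entry order of the
result is exactly the reference-set order: the reference set is the
coordinate system, so index stability is part of the contract.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .merge_sim import SimilarityParams, raw_similarity_detailed
from .netio import BioNetwork, ReferenceNetworkSet
from .ontology import SemanticBackground
from .randomize import (
    DEFAULT_NPERM,
    DEFAULT_SWAPS_PER_EDGE,
    RewireMode,
    null_distribution,
    standardize,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FingerprintEntry:
    group: str
    name: str
    raw_score: float
    null_mean: float
    null_sd: float
    standardized: float
    n_clusters: int


@dataclass
class FingerprintResult:
    """One fingerprint vector plus the run metadata needed to reproduce it."""

    query_name: str
    entries: list[FingerprintEntry]
    nperm: int
    seed: int
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self) -> list[tuple[str, str]]:
        return [(e.group, e.name) for e in self.entries]

    @property
    def standardized(self) -> np.ndarray:
        return np.array([e.standardized for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [e.group for e in self.entries],
                "name": [e.name for e in self.entries],
                "raw": [e.raw_score for e in self.entries],
                "null_mean": [e.null_mean for e in self.entries],
                "null_sd": [e.null_sd for e in self.entries],
                "standardized": [e.standardized for e in self.entries],
                "n_clusters": [e.n_clusters for e in self.entries],
            }
        )


def calc_fingerprint(
    query: BioNetwork,
    refset: ReferenceNetworkSet,
    ont: SemanticBackground,
    nperm: int = DEFAULT_NPERM,
    seed: int = 0,
    params: SimilarityParams | None = None,
    rewire_mode: RewireMode = "both",
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> FingerprintResult:
    """Compute the Network Fingerprint of ``query`` against ``refset``.

    For every reference network: merge + cluster + score the observed raw
    similarity, build a rewired null of ``nperm`` draws, and standardize.
    Fully deterministic at a fixed ``seed`` (one independent seed stream per
    reference).  Standardization dominates the runtime: each reference
    costs ``nperm + 1`` cluster-and-score passes.
    """
    if len(refset) == 0:
        raise ValueError("empty reference set")
    params = params or SimilarityParams()
    streams = np.random.SeedSequence(seed).spawn(len(refset))
    entries: list[FingerprintEntry] = []
    for entry, stream in zip(refset, streams):
        t0 = time.perf_counter()
        s_obs, s_null = (int(s) % 2**31 for s in stream.generate_state(2))
        try:
            detail = raw_similarity_detailed(query, entry.network, ont, params, seed=s_obs)
            null = null_distribution(
                query,
                entry.network,
                ont,
                params,
                nperm=nperm,
                seed=s_null,
                rewire_mode=rewire_mode,
                swaps_per_edge=swaps_per_edge,
            )
        except Exception as exc:
            raise RuntimeError(
                f"fingerprint failed at reference {entry.group}/{entry.name}: {exc}"
            ) from exc
        z = standardize(detail.score, null)
        entries.append(
            FingerprintEntry(
                group=entry.group,
                name=entry.name,
                raw_score=detail.score,
                null_mean=null.mean,
                null_sd=null.sd,
                standardized=z,
                n_clusters=detail.clusters.n_clusters,
            )
        )
        log.info(
            "reference %s/%s: raw=%.4g z=%.4g clusters=%d (%.2fs)",
            entry.group, entry.name, detail.score, z,
            detail.clusters.n_clusters, time.perf_counter() - t0,
        )
    return FingerprintResult(
        query_name=query.name,
        entries=entries,
        nperm=nperm,
        seed=seed,
        params=params.snapshot(),
    )


def top_fraction(
    fp: FingerprintResult, fraction: float
) -> list[tuple[str, str, float]]:
    """Top ``ceil(fraction * n)`` references by standardized score.

    Sorted descending; ties keep reference order.  ``fraction`` must lie in
    (0, 1]; e.g. 0.1 reports the top decile of the fingerprint.
    """
    if not fp.entries:
        raise ValueError("empty fingerprint")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(fp))
    ranked = sorted(
        enumerate(fp.entries), key=lambda pair: (-pair[1].standardized, pair[0])
    )
    return [(e.group, e.name, e.standardized) for _, e in ranked[:k]]


def export_table(fp: FingerprintResult, path) -> Path:
    """Write the fingerprint as TSV with a metadata header.

    Infinite standardized scores (degenerate nulls) serialize as
    ``inf`` / ``-inf`` so the table round-trips losslessly through
    :func:`load_table`.
    """
    path = Path(path)
    meta = {"query_name": fp.query_name, "nperm": fp.nperm, "seed": fp.seed,
            "params": fp.params}
    with open(path, "w") as fh:
        fh.write(f"# netfingerprint\t{json.dumps(meta)}\n")
        fp.to_frame().to_csv(fh, sep="\t", index=False)
    return path


def load_table(path) -> FingerprintResult:
    """Read a fingerprint table written by :func:`export_table`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# netfingerprint\t"):
            raise ValueError(f"{path}: not a fingerprint table (missing metadata header)")
        meta = json.loads(first.split("\t", 1)[1])
        # round_trip parser: standardized scores must reload bitwise-identical
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: fingerprint table has no entries")
    entries = [
        FingerprintEntry(
            group=str(r.group),
            name=str(r.name),
            raw_score=float(r.raw),
            null_mean=float(r.null_mean),
            null_sd=float(r.null_sd),
            standardized=float(r.standardized),
            n_clusters=int(r.n_clusters),
        )
        for r in df.itertuples(index=False)
    ]
    return FingerprintResult(
        query_name=meta["query_name"],
        entries=entries,
        nperm=int(meta["nperm"]),
        seed=int(meta["seed"]),
        params=meta.get("params", {}),
    )


@dataclass
class FingerprintComparison:
    """Long-format overlay table plus pairwise distance/correlation matrices."""

    long: pd.DataFrame
    euclidean: pd.DataFrame
    pearson: pd.DataFrame


def compare_fingerprints(fps: list[FingerprintResult]) -> FingerprintComparison:
    """Compare fingerprints computed against the same reference set.

    Returns a long table (query_name, group, reference_name, standardized)
    for overlay plotting, plus pairwise Euclidean distances and Pearson
    correlations between the fingerprint vectors.
    """
    if not fps:
        raise ValueError("no fingerprints to compare")
    keys = fps[0].keys()
    for fp in fps[1:]:
        if fp.keys() != keys:
            raise ValueError(
                f"fingerprint {fp.query_name!r} was computed against a different "
                f"reference set than {fps[0].query_name!r}"
            )
    rows = [
        (fp.query_name, e.group, e.name, e.standardized)
        for fp in fps
        for e in fp.entries
    ]
    long = pd.DataFrame(rows, columns=["query_name", "group", "reference_name", "standardized"])
    names = [fp.query_name for fp in fps]
    vecs = np.vstack([fp.standardized for fp in fps])
    diff = vecs[:, None, :] - vecs[None, :, :]
    eucl = pd.DataFrame(np.sqrt((diff**2).sum(-1)), index=names, columns=names)
    with np.errstate(invalid="ignore"):
        pear = pd.DataFrame(np.corrcoef(vecs), index=names, columns=names)
    return FingerprintComparison(long=long, euclidean=eucl, pearson=pear)


def plot_data(fp: FingerprintResult) -> pd.DataFrame:
    """Plot-ready table (index, name, group, standardized).

    Entries are arranged so each group occupies a contiguous 1-based index
    block (group order = first appearance in the reference set); rendering
    is left to the caller or :func:`plot_fingerprint`.
    """
    if not fp.entries:
        raise ValueError("empty fingerprint")
    group_order: list[str] = []
    for e in fp.entries:
        if e.group not in group_order:
            group_order.append(e.group)
    rows = []
    i = 0
    for g in group_order:
        for e in fp.entries:
            if e.group == g:
                i += 1
                rows.append((i, e.name, e.group, e.standardized))
    return pd.DataFrame(rows, columns=["index", "name", "group", "standardized"])


def plot_fingerprint(fp: FingerprintResult, ax=None, **line_kwargs):
    """Best-effort spectrum plot of one fingerprint (requires matplotlib).

    Draws the standardized scores over the reference index, colored per
    group; the tabular contract is :func:`plot_data`.
    """
    import matplotlib.pyplot as plt

    df = plot_data(fp)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(df) * 0.4), 4))
    for g, sub in df.groupby("group", sort=False):
        ax.plot(sub["index"], sub["standardized"], marker="o", label=g, **line_kwargs)
    ax.set_xlabel("reference network index")
    ax.set_ylabel("standardized similarity (z)")
    ax.set_title(f"Network Fingerprint: {fp.query_name}")
    ax.legend(title="group", fontsize="small")
    return ax
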