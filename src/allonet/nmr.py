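"""Integration of NMR chemical-shift and CPMG observables with communities.

Chemical-shift perturbations from an HSQC titration of a variant against the
wild type are combined into the composite

    ddelta = sqrt( 1/2 [ ddelta_H^2 + (ddelta_N / 5)^2 ] )   [ppm]

(amide nitrogen scaled by 1/5 to put it on the proton scale).  Significant
perturbations are those exceeding the 10% trimmed mean of all composite
shifts plus 1.5 standard deviations.  Residues whose peaks broaden beyond
detection carry no composite value and are reported separately.

CPMG relaxation dispersion flags mark residues undergoing us-ms exchange;
fitted R_ex values (when present) are differenced between variant and WT.
Overlaying the dispersive residues on a community partition yields an
exchange network whose weight for an adjacent community pair (A, B) is
n_active(A) * n_active(B), normalized by the squared total number of
CPMG-active residues -- a map of where slow dynamics couple communities.

Input tables are CSV with columns: residue, ddH_ppm, ddN_ppm, broadened,
dispersive, rex_s1 (missing columns default to inactive/NaN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .communities import CommunityPartition
from .corrnet import DynamicNetwork
from .errors import InputError

log = logging.getLogger(__name__)

TABLE_COLUMNS = ["residue", "ddH_ppm", "ddN_ppm", "broadened", "dispersive", "rex_s1"]
NITROGEN_SCALE = 5.0


def read_nmr_table(path) -> pd.DataFrame:
    """Read a shift/CPMG table, filling optional columns with defaults."""
    df = pd.read_csv(path)
    if "residue" not in df.columns:
        raise InputError(f"NMR table {path} lacks a 'residue' column")
    for col, default in [("ddH_ppm", np.nan), ("ddN_ppm", np.nan),
                         ("broadened", False), ("dispersive", False),
                         ("rex_s1", np.nan)]:
        if col not in df.columns:
            df[col] = default
    df["broadened"] = df["broadened"].astype(bool)
    df["dispersive"] = df["dispersive"].astype(bool)
    return df[TABLE_COLUMNS]


def composite_shift(dd_h, dd_n):
    """Composite chemical-shift perturbation in ppm (Bax scaling).

    Symmetric in the sign of either input and monotone in both magnitudes.
    """
    dd_h = np.asarray(dd_h, dtype=float)
    dd_n = np.asarray(dd_n, dtype=float)
    comp = np.sqrt(0.5 * (dd_h ** 2 + (dd_n / NITROGEN_SCALE) ** 2))
    return float(comp) if comp.ndim == 0 else comp


def add_composite(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``composite_ppm`` column; broadened residues get NaN."""
    out = df.copy()
    comp = composite_shift(out["ddH_ppm"].to_numpy(), out["ddN_ppm"].to_numpy())
    comp = np.where(out["broadened"].to_numpy(), np.nan, comp)
    out["composite_ppm"] = comp
    return out


@dataclass
class SignificanceResult:
    threshold: float
    trimmed_mean: float
    sigma: float
    significant: np.ndarray  # residue ids above threshold

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "trimmed_mean": self.trimmed_mean,
                "sigma": self.sigma, "significant": self.significant.tolist()}


def significance_cutoff(shifts, residue_ids=None, trim: float = 0.1,
                        n_sigma: float = 1.5,
                        sigma_over: str = "all") -> SignificanceResult:
    """Significance threshold for composite shifts: 10% trimmed mean + 1.5 sigma.

    Trimming drops the lowest and highest ``trim`` fraction (20% of the data
    in total at the default).  ``sigma_over`` chooses the set the standard
    deviation is taken over: ``"all"`` (default) uses every non-broadened
    composite shift, ``"trimmed"`` only the values surviving the trim.
    NaN entries (broadened residues) are excluded throughout.
    """
    x = np.asarray(shifts, dtype=float)
    if residue_ids is None:
        residue_ids = np.arange(1, len(x) + 1)
    residue_ids = np.asarray(residue_ids)
    keep = np.isfinite(x)
    x_kept, ids_kept = x[keep], residue_ids[keep]
    if len(x_kept) < 5:
        raise InputError(f"significance cutoff needs >=5 usable shifts, got {len(x_kept)}")
    tmean = float(stats.trim_mean(x_kept, trim))
    if sigma_over == "trimmed":
        lo, hi = np.percentile(x_kept, [100 * trim, 100 * (1 - trim)])
        pool = x_kept[(x_kept >= lo) & (x_kept <= hi)]
    elif sigma_over == "all":
        pool = x_kept
    else:
        raise InputError(f"sigma_over must be 'all' or 'trimmed', got {sigma_over!r}")
    sigma = float(np.std(pool, ddof=1))
    threshold = tmean + n_sigma * sigma
    return SignificanceResult(threshold=threshold, trimmed_mean=tmean, sigma=sigma,
                              significant=ids_kept[x_kept > threshold])


def delta_rex(variant: pd.DataFrame, wt: pd.DataFrame) -> pd.DataFrame:
    """Per-residue R_ex(variant) - R_ex(WT) on the residues with fitted values
    in both tables; residues present on one side only are excluded and logged.

    Returns a frame with columns residue, delta_rex; ``.attrs['mean_abs']``
    holds the mean |dR_ex|.
    """
    v = variant.dropna(subset=["rex_s1"]).set_index("residue")["rex_s1"]
    w = wt.dropna(subset=["rex_s1"]).set_index("residue")["rex_s1"]
    common = v.index.intersection(w.index)
    if len(common) == 0:
        raise InputError("variant and WT R_ex tables share no residues")
    skipped = sorted(set(v.index).symmetric_difference(w.index))
    if skipped:
        log.info("delta_rex: %d residue(s) present on one side only, excluded: %s",
                 len(skipped), skipped[:10])
    out = pd.DataFrame({"residue": common,
                        "delta_rex": (v[common] - w[common]).to_numpy()})
    out.attrs["mean_abs"] = float(np.abs(out["delta_rex"]).mean())
    return out


@dataclass
class ExchangeNetwork:
    """CPMG-community exchange map: normalized weights for adjacent pairs."""

    communities: list[int]
    weights: np.ndarray  # (C, C) normalized, symmetric, zero off non-adjacent
    active_counts: dict[int, int]
    normalization: float
    labels: dict[int, str] = field(default_factory=dict)

    def pair_weight(self, a: int, b: int) -> float:
        ia, ib = self.communities.index(a), self.communities.index(b)
        return float(self.weights[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.communities):
            for j in range(i + 1, len(self.communities)):
                b = self.communities[j]
                if self.weights[i, j] > 0:
                    rows.append({"community_a": self.labels.get(a, f"C{a}"),
                                 "community_b": self.labels.get(b, f"C{b}"),
                                 "weight": float(self.weights[i, j])})
        return pd.DataFrame(rows, columns=["community_a", "community_b", "weight"])


def community_adjacency(net: DynamicNetwork,
                        partition: CommunityPartition) -> set[tuple[int, int]]:
    """Community pairs sharing at least one network edge."""
    pairs = set()
    for u, v in net.graph.edges:
        a, b = partition.assignment[int(u)], partition.assignment[int(v)]
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    return pairs


def cpmg_exchange_network(cpmg: pd.DataFrame, partition: CommunityPartition,
                          adjacency: set[tuple[int, int]] | None = None,
                          net: DynamicNetwork | None = None,
                          normalization: str = "squared") -> ExchangeNetwork:
    """Exchange weight n_active(A) * n_active(B) for adjacent community pairs.

    ``normalization="squared"`` (default) divides by (total actives)^2 --
    invariant under uniform rescaling of the active counts; ``"total"``
    divides by the total count.  Adjacency is taken from ``adjacency`` or
    derived from ``net``'s inter-community edges.
    """
    if adjacency is None:
        if net is None:
            raise InputError("provide either an adjacency set or a DynamicNetwork")
        adjacency = community_adjacency(net, partition)
    adjacency = {(min(a, b), max(a, b)) for a, b in adjacency}
    active = cpmg.loc[cpmg["dispersive"], "residue"].astype(int).tolist()
    outside = [r for r in active if r not in partition.assignment]
    if outside:
        raise InputError(f"CPMG-active residues outside the partition: {sorted(outside)}")
    comms = partition.community_ids()
    counts = {c: 0 for c in comms}
    for r in active:
        counts[partition.assignment[r]] += 1
    total = sum(counts.values())
    if normalization == "squared":
        denom = float(total) ** 2
    elif normalization == "total":
        denom = float(total)
    else:
        raise InputError(f"unknown normalization {normalization!r}")
    index = {c: i for i, c in enumerate(comms)}
    weights = np.zeros((len(comms), len(comms)))
    if total > 0:
        for (a, b) in adjacency:
            w = counts[a] * counts[b] / denom
            weights[index[a], index[b]] = weights[index[b], index[a]] = w
    return ExchangeNetwork(communities=comms, weights=weights,
                           active_counts=counts, normalization=denom,
                           labels=dict(partition.labels))
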