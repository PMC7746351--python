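"""GISTIC-like copy-number scoring: arm-level gain/loss frequencies and
per-bin G-scores with a cyclic-shift permutation null, BH q-values and peak
calling.

The per-bin amplification G-score is the sum over samples of the (positive)
segment value of segments exceeding the amplification threshold that overlap
the bin; deletions symmetrically with negated values.  The null cyclically
shifts each sample's per-bin profile along the genome, which preserves each
sample's event sizes and amplitudes while destroying cross-sample alignment.
Thresholds default to the caller-relative ±1 convention; ``preset="gistic"``
switches to the conventional ±0.3 / ±1.3 log2-ratio-style bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_core import SegmentTable, ValidationError

logger = logging.getLogger("tmepipe")

PRESETS = {"cn1": (1.0, -1.0), "gistic": (0.3, -0.3)}


def arm_level(
    segs: SegmentTable,
    arms: pd.DataFrame,
    amp_thresh: float = 1.0,
    del_thresh: float = -1.0,
    arm_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-arm gain/loss frequency across samples.

    A sample carries an arm gain when segments with value > amp_thresh cover
    at least ``arm_frac`` of the arm's length (symmetric for loss).
    """
    for col in ("chrom", "arm", "start", "end"):
        if col not in arms.columns:
            raise ValidationError(f"arm table missing column {col!r}")
    samples = segs.sample_ids
    r = segs.records
    rows = []
    for _, arm in arms.iterrows():
        length = arm["end"] - arm["start"] + 1
        gains = losses = 0
        chrom_segs = r[r["Chromosome"] == arm["chrom"]]
        for s in samples:
            ss = chrom_segs[chrom_segs["Sample"] == s]
            ov_start = np.maximum(ss["Start"].to_numpy(), arm["start"])
            ov_end = np.minimum(ss["End"].to_numpy(), arm["end"])
            ov = np.maximum(ov_end - ov_start + 1, 0)
            vals = ss["Segment_Mean"].to_numpy(float)
            if ov[vals > amp_thresh].sum() >= arm_frac * length:
                gains += 1
            if ov[vals < del_thresh].sum() >= arm_frac * length:
                losses += 1
        rows.append({"arm": arm["arm"], "chrom": arm["chrom"],
                     "gain_freq": gains / len(samples),
                     "loss_freq": losses / len(samples)})
    return pd.DataFrame(rows).set_index("arm")


def make_bins(arms: pd.DataFrame, width: int = 1_000_000) -> pd.DataFrame:
    """Fixed-width genome bins covering the arm definition table."""
    rows = []
    for chrom, grp in arms.groupby("chrom", sort=False):
        lo = int(grp["start"].min())
        hi = int(grp["end"].max())
        for start in range(lo, hi + 1, width):
            rows.append({"chrom": chrom, "start": start,
                         "end": min(start + width - 1, hi)})
    return pd.DataFrame(rows)


def _bin_values(segs: SegmentTable, bins: pd.DataFrame) -> np.ndarray:
    """samples x bins matrix of segment values (max-|value| segment wins when
    several overlap a bin; 0 where uncovered)."""
    samples = segs.sample_ids
    sidx = {s: i for i, s in enumerate(samples)}
    n_bins = len(bins)
    out = np.zeros((len(samples), n_bins))
    chrom_bins = {c: np.flatnonzero((bins["chrom"] == c).to_numpy())
                  for c in bins["chrom"].unique()}
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    for rec in segs.records.itertuples(index=False):
        bi = chrom_bins.get(rec.Chromosome)
        if bi is None:
            continue
        hit = bi[(starts[bi] <= rec.End) & (ends[bi] >= rec.Start)]
        row = out[sidx[rec.Sample]]
        for b in hit:
            if abs(rec.Segment_Mean) > abs(row[b]):
                row[b] = rec.Segment_Mean
    return out


@dataclass
class GScoreProfile:
    bins: pd.DataFrame         # chrom, start, end, g_amp, g_del, q_amp, q_del
    arm_table: pd.DataFrame | None
    peaks: pd.DataFrame        # chrom, start, end, direction, q, peak_bin_start
    n_permutations: int
    seed: int


def gscore(
    segs: SegmentTable,
    bins: pd.DataFrame,
    amp_thresh: float = 1.0,
    del_thresh: float = -1.0,
    n_perm: int = 1000,
    q_threshold: float = 0.25,
    seed: int = 0,
    preset: str | None = None,
) -> GScoreProfile:
    """Per-bin amplification/deletion G-scores, permutation q-values, peaks.

    Empirical p-values pool the permuted scores over all bins (the cyclic
    null is exchangeable across bins), giving resolution ~1/(n_perm * n_bins).
    Peaks are maximal runs of bins with q below ``q_threshold``; each peak
    reports its maximal-G bin.
    """
    if preset is not None:
        amp_thresh, del_thresh = PRESETS[preset]
    V = _bin_values(segs, bins)  # samples x bins
    n_samples, n_bins = V.shape
    amp = np.where(V > amp_thresh, np.maximum(V, 0.0), 0.0)
    dele = np.where(V < del_thresh, np.maximum(-V, 0.0), 0.0)
    g_amp = amp.sum(0)
    g_del = dele.sum(0)

    rng = np.random.default_rng(seed)
    null_amp = np.empty((n_perm, n_bins))
    null_del = np.empty((n_perm, n_bins))
    for i in range(n_perm):
        pa = np.zeros(n_bins)
        pd_ = np.zeros(n_bins)
        for s in range(n_samples):
            shift = int(rng.integers(n_bins))
            pa += np.roll(amp[s], shift)
            pd_ += np.roll(dele[s], shift)
        null_amp[i] = pa
        null_del[i] = pd_
    pool_amp = np.sort(null_amp.ravel())
    pool_del = np.sort(null_del.ravel())

    def emp_p(obs, pool):
        # P(null >= obs) with add-one smoothing
        ge = len(pool) - np.searchsorted(pool, obs, side="left")
        return (ge + 1) / (len(pool) + 1)

    p_amp = emp_p(g_amp, pool_amp)
    p_del = emp_p(g_del, pool_del)
    covered = (V != 0).any(0)
    p_amp = np.where(covered, p_amp, 1.0)
    p_del = np.where(covered, p_del, 1.0)
    if (~covered).any():
        logger.info("gscore: %d bins with no coverage flagged q=1", int((~covered).sum()))
    q_amp = multipletests(p_amp, method="fdr_bh")[1]
    q_del = multipletests(p_del, method="fdr_bh")[1]

    table = bins.copy()
    table["g_amp"] = g_amp
    table["g_del"] = g_del
    table["p_amp"] = p_amp
    table["p_del"] = p_del
    table["q_amp"] = q_amp
    table["q_del"] = q_del

    peaks = []
    for direction, q, g in (("amp", q_amp, g_amp), ("del", q_del, g_del)):
        sig = q < q_threshold
        i = 0
        while i < n_bins:
            if sig[i]:
                j = i
                while (j + 1 < n_bins and sig[j + 1]
                       and bins.iloc[j + 1]["chrom"] == bins.iloc[i]["chrom"]):
                    j += 1
                block = slice(i, j + 1)
                top = i + int(np.argmax(g[block]))
                peaks.append({
                    "chrom": bins.iloc[i]["chrom"],
                    "start": int(bins.iloc[i]["start"]),
                    "end": int(bins.iloc[j]["end"]),
                    "direction": direction,
                    "q": float(q[block].min()),
                    "peak_bin_start": int(bins.iloc[top]["start"]),
                    "peak_g": float(g[top]),
                })
                i = j + 1
            else:
                i += 1
    return GScoreProfile(
        bins=table, arm_table=None,
        peaks=pd.DataFrame(peaks,
                           columns=["chrom", "start", "end", "direction", "q",
                                    "peak_bin_start", "peak_g"]),
        n_permutations=n_perm, seed=seed,
    )
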