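"""CAGE-peak simulation: a logistic model of TSS support plus empirical
resampling of peak geometry.

The probability that a transcript's TSS is supported by a CAGE peak is
modeled as

    Y_i ~ Bernoulli(pi_i),   logit(pi_i) = b0 + b1*X1_i + b2*X2_i

where X1 is the log TSS ratio (mean short-read coverage 100 bp downstream
of the TSS over 100 bp upstream, pseudocount-stabilized) and X2 the log
proportion of reads starting within a 20-bp window downstream of the TSS.
Peak geometry — (length, center-to-TSS distance) pairs — is resampled
jointly from two empirical groups, one for TSS-supporting peaks and one
for non-supporting peaks, preserving the length-distance dependence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .annotation_io import write_bed
from .model import TranscriptModel

PathLike = Union[str, Path]

TSS_RATIO_PSEUDOCOUNT = 0.01
TSS_WINDOW = 100  # bp each side for the TSS ratio
START_WINDOW = 20  # bp downstream window for the coverage proportion


def tss_ratio(
    coverage: np.ndarray,
    tss: int,
    strand: str,
    pseudocount: float = TSS_RATIO_PSEUDOCOUNT,
    window: int = TSS_WINDOW,
) -> float:
    """(mean depth 100 bp downstream + pc) / (mean depth 100 bp upstream + pc).

    ``coverage`` is a 0-based per-base depth array for the TSS's chromosome;
    ``tss`` is 1-based. Windows are oriented by strand and clipped at
    chromosome ends.
    """
    i = tss - 1
    n = len(coverage)
    if strand == "+":
        down = coverage[i : min(i + window, n)]
        up = coverage[max(i - window, 0) : i]
    else:
        down = coverage[max(i - window + 1, 0) : i + 1]
        up = coverage[i + 1 : min(i + 1 + window, n)]
    mean_down = float(down.mean()) if len(down) else 0.0
    mean_up = float(up.mean()) if len(up) else 0.0
    return (mean_down + pseudocount) / (mean_up + pseudocount)


def tss_coverage_proportion(
    read_starts: pd.DataFrame,
    chrom: str,
    tss: int,
    strand: str,
    window: int = START_WINDOW,
) -> float:
    """Fraction of all reads whose 5' start falls within a ``window``-bp
    window downstream of the TSS (strand-oriented, inclusive)."""
    total = len(read_starts)
    if total == 0:
        return 0.0
    sel = read_starts[
        (read_starts["chrom"] == chrom) & (read_starts["strand"] == strand)
    ]
    if strand == "+":
        n = int(((sel["pos"] >= tss) & (sel["pos"] <= tss + window - 1)).sum())
    else:
        n = int(((sel["pos"] <= tss) & (sel["pos"] >= tss - window + 1)).sum())
    return n / total


def compute_tss_features(
    transcripts: Sequence[TranscriptModel],
    coverage: dict[str, np.ndarray],
    read_starts: pd.DataFrame,
    cage_peaks: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-transcript (x1, x2) log features, plus the CAGE-support label y
    when observed peaks are supplied.

    x2's proportion is floored at 1/(2 * total reads) before the log so the
    feature stays finite for uncovered TSSs.
    """
    total = max(len(read_starts), 1)
    floor = 1.0 / (2.0 * total)
    rows = []
    for t in transcripts:
        x1 = math.log(tss_ratio(coverage[t.chrom], t.tss, t.strand))
        prop = tss_coverage_proportion(read_starts, t.chrom, t.tss, t.strand)
        x2 = math.log(max(prop, floor))
        y = np.nan
        if cage_peaks is not None:
            y = float(_tss_supported(cage_peaks, t.chrom, t.tss, t.strand))
        rows.append((t.transcript_id, t.chrom, t.tss, t.strand, x1, x2, y))
    return pd.DataFrame(
        rows, columns=["transcript_id", "chrom", "tss", "strand", "x1", "x2", "y"]
    )


def _tss_supported(peaks: pd.DataFrame, chrom: str, tss: int, strand: str) -> bool:
    sel = peaks[(peaks["chrom"] == chrom) & (peaks["strand"] == strand)]
    return bool(((sel["start"] <= tss) & (sel["end"] >= tss)).any())


@dataclass
class CageLogisticModel:
    """Fitted TSS-support logistic model plus peak-geometry resampling pools."""

    beta0: float
    beta1: float
    beta2: float
    supporting_pairs: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2))
    )  # columns: length, signed center-to-TSS distance
    nonsupporting_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    nonsupporting_proportion: float = 0.0
    cv_accuracy: Optional[float] = None

    def predict_pi(self, x1, x2):
        """pi = expit(b0 + b1*x1 + b2*x2); exact closed form of the link."""
        z = self.beta0 + self.beta1 * np.asarray(x1) + self.beta2 * np.asarray(x2)
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self, path: PathLike) -> None:
        payload = {
            "beta": [self.beta0, self.beta1, self.beta2],
            "supporting_pairs": np.asarray(self.supporting_pairs).tolist(),
            "nonsupporting_pairs": np.asarray(self.nonsupporting_pairs).tolist(),
            "nonsupporting_proportion": self.nonsupporting_proportion,
            "cv_accuracy": self.cv_accuracy,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: PathLike) -> "CageLogisticModel":
        d = json.loads(Path(path).read_text())
        return cls(
            beta0=d["beta"][0],
            beta1=d["beta"][1],
            beta2=d["beta"][2],
            supporting_pairs=np.asarray(d["supporting_pairs"], dtype=float).reshape(-1, 2),
            nonsupporting_pairs=np.asarray(d["nonsupporting_pairs"], dtype=float).reshape(-1, 2),
            nonsupporting_proportion=d["nonsupporting_proportion"],
            cv_accuracy=d.get("cv_accuracy"),
        )

    @classmethod
    def synthetic_default(cls, seed: int = 12345) -> "CageLogisticModel":
        """A synthetic stand-in model (no pre-trained real-data model is
        shipped): moderate positive dependence of support on both features
        and plausible peak geometry pools."""
        rng = np.random.default_rng(seed)
        sup_len = np.clip(rng.lognormal(math.log(60), 0.5, 400), 10, 500)
        sup_dist = rng.normal(0, 15, 400)
        non_len = np.clip(rng.lognormal(math.log(40), 0.6, 400), 10, 500)
        non_dist = rng.normal(0, 400, 400)
        return cls(
            beta0=1.0,
            beta1=0.8,
            beta2=0.5,
            supporting_pairs=np.column_stack([sup_len, sup_dist]),
            nonsupporting_pairs=np.column_stack([non_len, non_dist]),
            nonsupporting_proportion=0.3,
        )


def fit_cage_model(
    features: pd.DataFrame,
    cage_peaks: Optional[pd.DataFrame] = None,
    tss_table: Optional[pd.DataFrame] = None,
    folds: int = 5,
    seed: int = 0,
) -> CageLogisticModel:
    """Maximum-likelihood logistic fit of y on (x1, x2) with k-fold
    cross-validated accuracy; peak-geometry pools are derived from the
    supplied observed peaks split by TSS-overlap status."""
    y = features["y"].to_numpy(dtype=float)
    if np.unique(y[~np.isnan(y)]).size < 2:
        raise ValueError("logistic fit needs both supported and unsupported TSSs")
    X = features[["x1", "x2"]].to_numpy(dtype=float)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    clf.fit(X, y)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = float(
        cross_val_score(
            LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000),
            X,
            y,
            cv=cv,
            scoring="accuracy",
        ).mean()
    )
    model = CageLogisticModel(
        beta0=float(clf.intercept_[0]),
        beta1=float(clf.coef_[0][0]),
        beta2=float(clf.coef_[0][1]),
        cv_accuracy=acc,
    )
    if cage_peaks is not None and tss_table is not None:
        sup, non = _split_peak_pairs(cage_peaks, tss_table)
        model.supporting_pairs = sup
        model.nonsupporting_pairs = non
        n_tot = len(sup) + len(non)
        model.nonsupporting_proportion = len(non) / n_tot if n_tot else 0.0
    return model


def _split_peak_pairs(
    peaks: pd.DataFrame, tss_table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(length, strand-signed center-to-nearest-TSS distance) pairs, split
    by whether the peak overlaps any TSS on its strand."""
    sup, non = [], []
    for _, p in peaks.iterrows():
        cands = tss_table[
            (tss_table["chrom"] == p["chrom"]) & (tss_table["strand"] == p["strand"])
        ]
        if cands.empty:
            continue
        length = int(p["end"] - p["start"] + 1)
        center = (p["start"] + p["end"]) / 2.0
        deltas = center - cands["tss"].to_numpy(dtype=float)
        nearest = deltas[np.argmin(np.abs(deltas))]
        signed = nearest if p["strand"] == "+" else -nearest
        overlaps = bool(
            ((cands["tss"] >= p["start"]) & (cands["tss"] <= p["end"])).any()
        )
        (sup if overlaps else non).append((length, signed))
    return (
        np.asarray(sup, dtype=float).reshape(-1, 2),
        np.asarray(non, dtype=float).reshape(-1, 2),
    )


def simulate_cage_peaks(
    model: CageLogisticModel,
    features: pd.DataFrame,
    seed: int = 0,
    bed_path: Optional[PathLike] = None,
    nonsupporting_proportion: Optional[float] = None,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Simulate a CAGE-peak BED for the given TSS feature table.

    Per TSS, support is Bernoulli(pi) from the logistic model; supporting
    peaks get a (length, distance) pair resampled from the supporting pool
    and are placed so the interval overlaps the TSS. Additional
    non-supporting peaks are emitted to reach the requested proportion,
    placed at a resampled distance from a random TSS, overlap disallowed.
    """
    p_non = (
        model.nonsupporting_proportion
        if nonsupporting_proportion is None
        else nonsupporting_proportion
    )
    if not 0.0 <= p_non < 1.0:
        raise ValueError("non-supporting proportion must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    pi = model.predict_pi(features["x1"].to_numpy(), features["x2"].to_numpy())
    support = rng.random(len(pi)) < pi

    rows = []
    for (_, f), sup in zip(features.iterrows(), support):
        if not sup or len(model.supporting_pairs) == 0:
            continue
        length, dist = model.supporting_pairs[
            rng.integers(len(model.supporting_pairs))
        ]
        length = max(int(round(length)), 1)
        dist = dist if f["strand"] == "+" else -dist
        center = int(round(f["tss"] + dist))
        start = center - length // 2
        end = start + length - 1
        # the defining property of a supporting peak is TSS overlap: clip
        if not (start <= f["tss"] <= end):
            shift = int(f["tss"]) - (start if f["tss"] < start else end)
            start += shift
            end += shift
        start, end = _clip_chrom(start, end, f["chrom"], chrom_lengths)
        rows.append((f["chrom"], start, end, f["strand"], True, f["transcript_id"]))

    n_sup = len(rows)
    n_non = int(round(n_sup * p_non / (1.0 - p_non))) if n_sup else 0
    tss_by_pos = features[["chrom", "tss", "strand"]].to_numpy(dtype=object)
    for _ in range(n_non):
        if len(model.nonsupporting_pairs) == 0 or len(tss_by_pos) == 0:
            break
        chrom, tss, strand = tss_by_pos[rng.integers(len(tss_by_pos))]
        length, dist = model.nonsupporting_pairs[
            rng.integers(len(model.nonsupporting_pairs))
        ]
        length = max(int(round(length)), 1)
        dist = dist if strand == "+" else -dist
        center = int(round(tss + dist))
        start = center - length // 2
        end = start + length - 1
        if start <= tss <= end:  # overlap disallowed: shift just past the TSS
            start = int(tss) + 1
            end = start + length - 1
        start, end = _clip_chrom(start, end, chrom, chrom_lengths)
        rows.append((chrom, start, end, strand, False, None))

    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "supporting", "tss_id"]
    )
    if bed_path is not None:
        write_bed(
            (
                (r.chrom, int(r.start), int(r.end), f"peak_{i}", 1.0, r.strand)
                for i, r in enumerate(peaks.itertuples())
            ),
            bed_path,
        )
    return peaks


def _clip_chrom(start, end, chrom, chrom_lengths):
    start = max(int(start), 1)
    end = int(end)
    if chrom_lengths and chrom in chrom_lengths:
        end = min(end, chrom_lengths[chrom])
        start = min(start, end)
    return start, max(end, start)
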