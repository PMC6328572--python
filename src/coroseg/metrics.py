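"""Segmentation-agreement metrics, pooled over structures or plaques.

All overlap metrics pool voxel counts over the list of test/reference pairs
before forming the ratio (not the mean of per-pair ratios):

* DICE     = 2 sum_i |Vt_i ^ Vr_i| / sum_i (|Vt_i| + |Vr_i|) x 100
* VolMSE   = (1/n) sum_i (vol(Vt_i) - vol(Vr_i))^2, volumes in mm^3
* RelVolErr= sum_i |vol(Vt_i) - vol(Vr_i)| / sum_i vol(Vr_i) x 100
* PREC     = sum_i |Vt_i ^ Vr_i| / sum_i |Vt_i| x 100
* SENS     = sum_i |Vt_i ^ Vr_i| / sum_i |Vr_i| x 100

VolMSE squares mm^3 volumes; it is reported with an mm^3 label to match the
convention of the published tables, and the squared nature of the quantity
is documented rather than silently rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import BinaryMask


@dataclass
class VolumePairSet:
    """Paired test/reference masks (one pair per plaque or structure)."""

    test_volumes: list[BinaryMask]
    reference_volumes: list[BinaryMask]

    def __post_init__(self):
        if len(self.test_volumes) != len(self.reference_volumes):
            raise ValueError("test and reference lists must have equal length")
        if not self.test_volumes:
            raise ValueError("at least one pair is required")
        for t, r in zip(self.test_volumes, self.reference_volumes):
            if t.grid != r.grid:
                raise ValueError("each test/reference pair must share one grid")

    @classmethod
    def single(cls, test: BinaryMask, reference: BinaryMask) -> "VolumePairSet":
        return cls([test], [reference])

    def _counts(self):
        inter = np.array([int((t.data & r.data).sum())
                          for t, r in zip(self.test_volumes, self.reference_volumes)])
        nt = np.array([t.count for t in self.test_volumes])
        nr = np.array([r.count for r in self.reference_volumes])
        return inter, nt, nr

    def _volumes_mm3(self):
        vt = np.array([t.volume_mm3 for t in self.test_volumes])
        vr = np.array([r.volume_mm3 for r in self.reference_volumes])
        return vt, vr


@dataclass
class MetricsReport:
    dice_pct: float
    vol_mse: float            # squared mm^3 deviation, labelled mm^3 in tables
    rel_vol_error_pct: float
    precision_pct: float
    sensitivity_pct: float
    per_item: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"dice_pct": self.dice_pct, "vol_mse": self.vol_mse,
                "rel_vol_error_pct": self.rel_vol_error_pct,
                "precision_pct": self.precision_pct,
                "sensitivity_pct": self.sensitivity_pct,
                "per_item": self.per_item}


def dice(pairs: VolumePairSet) -> float:
    inter, nt, nr = pairs._counts()
    denom = nt.sum() + nr.sum()
    if denom == 0:
        raise ValueError("DICE undefined: all test and reference volumes are empty")
    return 200.0 * inter.sum() / denom


def volume_mse(pairs: VolumePairSet) -> float:
    vt, vr = pairs._volumes_mm3()
    return float(np.mean((vt - vr) ** 2))


def relative_volume_error(pairs: VolumePairSet) -> float:
    vt, vr = pairs._volumes_mm3()
    if vr.sum() == 0:
        raise ValueError("relative volume error undefined: reference volumes are empty")
    return float(np.abs(vt - vr).sum() / np.abs(vr).sum() * 100.0)


def precision_sensitivity(pairs: VolumePairSet) -> tuple[float, float]:
    inter, nt, nr = pairs._counts()
    if nt.sum() == 0:
        raise ValueError("precision undefined: test volumes are empty")
    if nr.sum() == 0:
        raise ValueError("sensitivity undefined: reference volumes are empty")
    return (100.0 * inter.sum() / nt.sum(), 100.0 * inter.sum() / nr.sum())


def report(pairs: VolumePairSet) -> MetricsReport:
    """All five pooled metrics plus the per-pair breakdown."""
    prec, sens = precision_sensitivity(pairs)
    per = []
    for t, r in zip(pairs.test_volumes, pairs.reference_volumes):
        one = VolumePairSet.single(t, r)
        p, s = precision_sensitivity(one)
        per.append({"dice_pct": dice(one), "vol_mse": volume_mse(one),
                    "rel_vol_error_pct": relative_volume_error(one),
                    "precision_pct": p, "sensitivity_pct": s})
    return MetricsReport(dice_pct=dice(pairs), vol_mse=volume_mse(pairs),
                         rel_vol_error_pct=relative_volume_error(pairs),
                         precision_pct=prec, sensitivity_pct=sens, per_item=per)


def bland_altman(test_vols, ref_vols) -> dict:
    """Bias and 95% limits of agreement for paired volumes (mm^3)."""
    t = np.asarray(test_vols, float)
    r = np.asarray(ref_vols, float)
    if t.shape != r.shape or t.size < 2:
        raise ValueError("need two equal-length lists with at least 2 entries")
    diff = t - r
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {"bias": bias, "sd": sd,
            "limits": (bias - 1.96 * sd, bias + 1.96 * sd),
            "mean": ((t + r) / 2.0).tolist(), "diff": diff.tolist()}


def crop_arc_window(straight_mask_stack: np.ndarray, arc_length: np.ndarray,
                    start_mm: float, end_mm: float) -> np.ndarray:
    """Restrict a straightened mask stack to an arc-length window.

    Used to carve per-plaque masks out of the straightened wall between
    user-supplied proximal/distal bounds.
    """
    keep = (arc_length >= start_mm) & (arc_length <= end_mm)
    out = np.zeros_like(straight_mask_stack, dtype=bool)
    out[keep] = straight_mask_stack[keep]
    return out


def quartile_grouped_reports(pairs: VolumePairSet, lengths_mm) -> list[dict]:
    """Pool the metrics within quartiles of plaque length."""
    lengths = np.asarray(lengths_mm, float)
    if len(lengths) != len(pairs.test_volumes):
        raise ValueError("one length per pair is required")
    qs = np.quantile(lengths, [0.25, 0.5, 0.75])
    group = np.digitize(lengths, qs)
    out = []
    for q in range(4):
        sel = group == q
        if not sel.any():
            out.append({"quartile": q + 1, "n": 0})
            continue
        sub = VolumePairSet([t for t, k in zip(pairs.test_volumes, sel) if k],
                            [r for r, k in zip(pairs.reference_volumes, sel) if k])
        rep = report(sub).as_dict()
        rep.update(quartile=q + 1, n=int(sel.sum()))
        rep.pop("per_item")
        out.append(rep)
    return out
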