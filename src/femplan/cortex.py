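"""Anterior cortex points: the sizing (saddle) point and the FRAC point.

The lateral anterior ridge of the distal femur is traced as a polyline of
the most anterior surface points over transverse sections proximal to the
trochlear groove.  Its anteroposterior height profile h(s) is convex over
the distal part and turns concave proximally; the *sizing point* is that
convex-to-concave inflection (what a surgical sizing guide lands on).

The *FRAC point* (femoral resection anterior cortex point) is searched
between the lowest and highest points on the ridge: for each candidate
the anterior flange plane is placed through it and the resulting
anterior-cortex notching, anterior undercut area and AP-cut balance are
evaluated; the most posterior notch-free candidate wins — anterior
referencing at that point removes a complete anterior resection surface
without violating the cortex proximal to the flange.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import AnatomicalFrame, compute_condylar_landmarks
from .geometry import Plane
from .placement import PlacementConfig, build_resection_planes
from .resection import (
    NOTCH_GATE,
    detect_notching,
    flatten_contour,
    intersect_mesh_plane,
)

__all__ = [
    "RidgeProfile",
    "CortexPoints",
    "ProfileError",
    "NoSaddleError",
    "extract_ridge_profile",
    "compute_sizing_point",
    "compute_frac_point",
    "RIDGE_WINDOW",
]

#: ridge search span, mm proximal of the posterior condylar level
RIDGE_WINDOW = (17.0, 33.0)
#: arclength resampling step of the ridge polyline (mm); also the FRAC
#: candidate step
PROFILE_STEP = 0.5
#: moving-average smoothing window applied to h(s) before curvature (mm)
SMOOTH_WINDOW = 8.0


class ProfileError(RuntimeError):
    """Ridge profile could not be extracted."""


class NoSaddleError(RuntimeError):
    """The smoothed profile has no convex-to-concave inflection."""


@dataclass
class RidgeProfile:
    """Ordered ridge polyline, distal to proximal, with its AP signal."""

    points: np.ndarray            # (n, 3) resampled polyline
    s: np.ndarray                 # (n,) arclength, strictly increasing
    h: np.ndarray                 # (n,) raw AP height (frame AP projection)
    h_smooth: np.ndarray          # (n,) moving-average smoothed signal
    frame: AnatomicalFrame

    def __post_init__(self):
        if len(self.s) < 20:
            raise ProfileError(f"ridge profile too short ({len(self.s)} samples)")
        if np.any(np.diff(self.s) <= 0):
            raise ProfileError("arclength must be strictly increasing")

    @classmethod
    def from_polyline(cls, points: np.ndarray, frame: AnatomicalFrame,
                      step: float = PROFILE_STEP) -> "RidgeProfile":
        points = np.asarray(points, float)
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        s_raw = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.arange(0.0, s_raw[-1] + step / 2, step)
        pts = np.column_stack([np.interp(s, s_raw, points[:, k]) for k in range(3)])
        h = (pts - frame.origin) @ frame.AP
        half = max(1, int(round(SMOOTH_WINDOW / (2 * step))))
        kernel = np.ones(2 * half + 1) / (2 * half + 1)
        padded = np.concatenate([h[half:0:-1], h, h[-2:-half - 2:-1]])
        h_smooth = np.convolve(padded, kernel, mode="valid")
        return cls(points=pts, s=s, h=h, h_smooth=h_smooth, frame=frame)

    def at(self, s_query: float) -> np.ndarray:
        return np.array([np.interp(s_query, self.s, self.points[:, k]) for k in range(3)])


@dataclass
class CortexPoints:
    sizing_point: np.ndarray
    ridge_high: np.ndarray
    ridge_low: np.ndarray
    frac_point: np.ndarray | None = None
    frac_warning: bool = False
    frac_search_trace: list = field(default_factory=list)
    profile: RidgeProfile | None = None

    def reference(self, which: str) -> np.ndarray:
        which = which.upper()
        if which == "FRAC":
            if self.frac_point is None:
                raise ValueError("FRAC point has not been computed")
            return self.frac_point
        if which == "SIZING":
            return self.sizing_point
        if which == "RIDGE_AVERAGE":
            return 0.5 * (self.ridge_high + self.ridge_low)
        raise ValueError(f"unknown anterior reference {which!r}")

    def to_dict(self) -> dict:
        out = {
            "sizing_point": self.sizing_point.tolist(),
            "ridge_high": self.ridge_high.tolist(),
            "ridge_low": self.ridge_low.tolist(),
            "frac_point": None if self.frac_point is None else self.frac_point.tolist(),
            "frac_warning": self.frac_warning,
            "frac_search_trace": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in rec.items()}
                for rec in self.frac_search_trace
            ],
        }
        return out


# --------------------------------------------------------------------------


def extract_ridge_profile(mesh, frame: AnatomicalFrame, landmarks=None,
                          ml_min: float | None = None,
                          spacing: float = 1.0) -> RidgeProfile:
    """Trace the lateral anterior ridge proximal to the trochlear groove.

    For each transverse section across the search window the most
    anterior surface point lateral of ``ml_min`` (default: 2 mm lateral
    of the sulcus) is taken; near-extremal vertices are averaged to tame
    tessellation noise.  The chained polyline is resampled at 0.5 mm
    arclength.
    """
    landmarks = landmarks or compute_condylar_landmarks(mesh, frame)
    if ml_min is None:
        from .axes import extract_groove_plane

        groove = extract_groove_plane(mesh, frame, landmarks)
        ml_min = float((groove.origin - frame.origin) @ frame.ML) + 2.0
    v = mesh.vertices.view(np.ndarray)
    coords = frame.project(v)
    ml, ap, pd = coords.T
    post_pd = 0.5 * (frame.project(landmarks.posterior_medial)[0, 2]
                     + frame.project(landmarks.posterior_lateral)[0, 2])
    lo, hi = post_pd + RIDGE_WINDOW[0], post_pd + RIDGE_WINDOW[1]
    stations = np.arange(lo, hi + spacing / 2, spacing)
    if len(stations) < 2:
        raise ProfileError("ridge window empty")

    def trace(ml_lo: float, ml_hi: float) -> tuple[list, list]:
        pts, mls = [], []
        for s0 in stations:
            sel = (np.abs(pd - s0) < 0.8) & (ml > ml_lo) & (ml < ml_hi)
            if sel.sum() < 3:
                continue
            sub_ap = ap[sel]
            sub_ml = ml[sel]
            top = sub_ap.max()
            plateau = v[sel][sub_ap > top - 0.3]
            point = plateau.mean(axis=0)
            ml_p, ap_p, _ = frame.project(point)[0]
            # the ridge crest is crowned; a parabola through the near-top
            # points pins the apex far better than a plateau average,
            # keeping the polyline from wandering mediolaterally
            near = sub_ap > top - 2.5
            if near.sum() >= 5:
                a, b, c = np.polyfit(sub_ml[near], sub_ap[near], 2)
                if a < -1e-4:
                    ml_hat = float(np.clip(-b / (2 * a), sub_ml[near].min(),
                                           sub_ml[near].max()))
                    ap_hat = a * ml_hat * ml_hat + b * ml_hat + c
                    point = point + (ml_hat - ml_p) * frame.ML + (ap_hat - ap_p) * frame.AP
                    ml_p = ml_hat
            pts.append(point)
            mls.append(float(ml_p))
        return pts, mls

    # two passes: the first locates the ridge crest laterally, the second
    # restricts to a band around it so nearby anterior shaft cortex never
    # captures the most-anterior pick on proximal sections
    pts, mls = trace(ml_min, np.inf)
    if len(pts) >= 5:
        center = float(np.median(mls))
        pts, _ = trace(max(ml_min, center - 6.0), center + 6.0)
    if len(pts) < 10:
        raise ProfileError("too few ridge sections")
    return RidgeProfile.from_polyline(np.array(pts), frame)


def compute_sizing_point(profile: RidgeProfile) -> np.ndarray:
    """Saddle point: first convex-to-concave inflection, distal to proximal.

    Works on the second difference of the smoothed AP signal; the
    crossing is rejected unless curvature is consistently negative before
    and positive after it, which filters single-sample noise.
    """
    h = profile.h_smooth
    d2 = np.diff(h, 2)
    # tessellation noise survives into the second difference; smooth the
    # curvature signal and demand an amplitude-relative sign contrast so
    # wiggles on the flat crest cannot masquerade as the saddle
    win = min(9, max(3, (len(d2) // 4) | 1))
    kernel = np.ones(win) / win
    padded = np.concatenate([d2[win // 2:0:-1], d2, d2[-2:-win // 2 - 2:-1]])
    d2s = np.convolve(padded, kernel, mode="valid")
    margin = 5
    core = d2s[margin:-margin] if len(d2s) > 2 * margin else d2s
    tol = max(1e-8, 0.1 * np.abs(core).max())
    for i in range(margin, len(d2s) - margin - 1):
        if d2s[i] <= 0.0 < d2s[i + 1]:
            before = d2s[max(0, i - 9):i + 1]
            after = d2s[i + 1:i + 11]
            if before.mean() < -tol and after.mean() > tol:
                # linear interpolation of the zero crossing; d2s[i] sits at s[i+1]
                frac = -d2s[i] / (d2s[i + 1] - d2s[i]) if d2s[i + 1] != d2s[i] else 0.0
                s_star = profile.s[i + 1] + frac * (profile.s[i + 2] - profile.s[i + 1])
                return profile.at(s_star)
    raise NoSaddleError("profile too short for curvature estimation")
    step = float(np.mean(np.diff(profile.s)))
    d2s = savgol_filter(h, window_length=wl, polyorder=3, deriv=2, delta=step)
    margin = 5
    core = d2s[margin:-margin] if len(d2s) > 2 * margin else d2s
    tol = max(1e-8, 0.1 * np.abs(core).max())
    for i in range(margin, len(d2s) - margin - 1):
        if d2s[i] <= 0.0 < d2s[i + 1]:
            before = d2s[max(0, i - 9):i + 1]
            after = d2s[i + 1:i + 11]
            if before.mean() < -tol and after.mean() > tol:
                frac = -d2s[i] / (d2s[i + 1] - d2s[i]) if d2s[i + 1] != d2s[i] else 0.0
                s_star = profile.s[i] + frac * (profile.s[i + 1] - profile.s[i])
                return profile.at(s_star)
    raise NoSaddleError("no convex-to-concave inflection in the ridge profile")


def _ridge_extremes(profile: RidgeProfile) -> tuple[int, int]:
    """Indices of the ridge high (max AP) and low (min AP) samples.

    The profile is flat near its extremes, so the *most distal* sample
    within 0.1 mm of the maximum and the *most proximal* sample within
    0.1 mm of the minimum are used — deterministic on a plateau.
    """
    h = profile.h_smooth
    i_high = int(np.flatnonzero(h > h.max() - 0.1)[0])
    i_low = int(np.flatnonzero(h < h.min() + 0.1)[-1])
    return i_high, i_low


def _select_frac(trace: list) -> tuple[dict, bool]:
    """FRAC selection rule on an evaluated candidate trace.

    The most posterior (lowest AP height) candidate with no notch wins;
    if every candidate notches, the minimal-depth one is returned with a
    warning flag.
    """
    order = sorted(trace, key=lambda r: r["h"])
    feasible = [r for r in order if r["notch_depth"] <= NOTCH_GATE]
    if feasible:
        return feasible[0], False
    return min(order, key=lambda r: r["notch_depth"]), True


def _undercut_area(mesh, planes, implant) -> float:
    """Anterior flange area left unsupported by bone (mm^2)."""
    flange = implant.footprint_polygon("anterior")
    contour = intersect_mesh_plane(mesh, planes.anterior)
    if not contour.loops:
        return float(flange.area)
    bone = flatten_contour(contour).union
    return float(flange.area - flange.intersection(bone).area)


def compute_frac_point(mesh, frame: AnatomicalFrame, axes, implant,
                       config: PlacementConfig,
                       profile: RidgeProfile | None = None,
                       landmarks=None) -> CortexPoints:
    """FRAC search: most posterior notch-free point on the lateral ridge.

    Every profile sample between the ridge low and high points is tried
    as the anterior reference; notch depth, anterior undercut area and
    the AP balance metric |mean anterior thickness - flange thickness|
    are recorded for each.  If no candidate is notch-free the one with
    minimal notch depth is returned with a warning flag.
    """
    from .resection import measure_thicknesses

    landmarks = landmarks or compute_condylar_landmarks(mesh, frame)
    profile = profile or extract_ridge_profile(mesh, frame, landmarks)
    sizing = compute_sizing_point(profile)
    i_high, i_low = _ridge_extremes(profile)
    lo, hi = min(i_high, i_low), max(i_high, i_low)
    idx = list(range(lo, hi + 1))
    if not idx:
        raise ProfileError("empty FRAC candidate set")
    # distal cut (hence ML centring) does not depend on the candidate
    from .placement import _distal_ml_center

    probe = build_resection_planes(mesh, axes, implant, profile.points[idx[0]], config)
    ml_center = _distal_ml_center(mesh, probe.distal)

    trace = []
    for i in idx:
        cand = profile.points[i]
        planes = build_resection_planes(mesh, axes, implant, cand, config,
                                        ml_center=ml_center)
        notch = detect_notching(mesh, planes.anterior, planes.flange_proximal_pd, frame)
        under = _undercut_area(mesh, planes, implant)
        th = measure_thicknesses(planes, landmarks)
        balance = abs(0.5 * (th.FACL + th.FACM) - implant.flange_thickness)
        trace.append({
            "s": float(profile.s[i]),
            "candidate": cand,
            "h": float(profile.h[i]),
            "notch_depth": float(notch.notch_depth),
            "undercut_area": under,
            "balance": float(balance),
        })
    best, warning = _select_frac(trace)
    return CortexPoints(
        sizing_point=sizing,
        ridge_high=profile.points[i_high],
        ridge_low=profile.points[i_low],
        frac_point=np.asarray(best["candidate"], float),
        frac_warning=warning,
        frac_search_trace=trace,
        profile=profile,
    )
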