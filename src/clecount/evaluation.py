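"""End-to-end evaluation harness on synthetic data.

Every function here runs the package's own public pipeline on seeded
synthetic inputs and measures a property a user would care about
before trusting the counter on real video: statistical components
against independent oracles, granulometric size recovery, detection
precision/recall against simulator ground truth, count-rate recovery
through the full pipeline, study-level power and type-I behavior of the
group comparison, and byte-level reproducibility.

The study-power harness runs at a reduced geometry (128 x 128 frames,
24 frames per video) so hundreds of replicate studies fit on a desktop;
detection percentiles are re-resolved for that geometry as described in
docs/methods.md.
"""

from __future__ import annotations

import itertools
import json
import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np
from scipy import stats

from .detection import count_frame, calibration_enhance, compute_granulometry
from .core import Frame
from .io import write_counts_csv, write_video_tiff
from .params import DetectionParams
from .quantify import compare_groups, concordance_correlation, mann_whitney, quantify_video
from .simulate import (
    GroupSpec,
    SimulationConfig,
    generate_study,
    generate_video,
    iter_video_frames,
    score_detections,
)

#: Detection parameters for the default 512 x 512 study geometry.
DEFAULT_PARAMS = DetectionParams(se_radius=2)

#: Detection parameters re-resolved for the reduced 128 x 128 geometry
#: used by the replicate-study harness: the two upper percentiles track
#: the expected foreground fraction, which grows as the field shrinks.
REDUCED_PARAMS = DetectionParams(
    se_radius=2, enhance_high_pct=97.0, thr_low=0.95, min_area=21, max_area=403
)

MATCH_RADIUS = 5.0  # one nominal cell radius, for centroid matching


def _spawn(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1, dtype=np.uint32)[0] % (2**31)) for c in children]


# ---------------------------------------------------------------------------
# statistical components vs independent oracles


def ccc_against_oracle(n_pairs: int = 1000, seed: int = 0) -> dict:
    """Max |CCC - oracle| over random count pairs, plus |CCC| <= |r| checks.

    The oracle is the Pearson-correlation form of Lin's coefficient,
    2 r sx sy / (sx^2 + sy^2 + (mx - my)^2), computed with scipy.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    exceeds_pearson = 0
    for _ in range(n_pairs):
        n = int(rng.integers(2, 60))
        x = rng.poisson(rng.uniform(0.5, 8.0), size=n).astype(float)
        y = x + rng.normal(0, rng.uniform(0.1, 2.0), size=n)
        res = concordance_correlation(x, y)
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            r = 0.0
        else:
            r = stats.pearsonr(x, y).statistic
        oracle = 2 * r * sx * sy / (sx**2 + sy**2 + (x.mean() - y.mean()) ** 2)
        max_err = max(max_err, abs(res.ccc - oracle))
        if abs(res.ccc) > abs(r) + 1e-12:
            exceeds_pearson += 1
    return {"max_abs_err": max_err, "ccc_exceeds_pearson": exceeds_pearson}


def _mw_oracle_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumeration with direct pairwise counting."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(a) + len(b)

    def u_of(idx: tuple[int, ...]) -> float:
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        return float((ga[:, None] > gb[None, :]).sum()) + 0.5 * float(
            (ga[:, None] == gb[None, :]).sum()
        )

    mu = na * (n - na) / 2.0
    d_obs = abs(u_of(tuple(range(na))) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        total += 1
        if abs(u_of(combo) - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_against_enumeration(seed: int = 0, reps_per_size: int = 3) -> dict:
    """Max |p - enumeration oracle| over all tie-free designs with n <= 10."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    u_identity_violations = 0
    for na in range(1, 10):
        for nb in range(1, 11 - na):
            for _ in range(reps_per_size):
                a = rng.normal(size=na)
                b = rng.normal(size=nb)
                res = mann_whitney(a, b)
                max_err = max(max_err, abs(res.p_value - _mw_oracle_p(a, b)))
                ub = mann_whitney(b, a).u_statistic
                if abs(res.u_statistic + ub - na * nb) > 1e-9:
                    u_identity_violations += 1
    return {"max_abs_err": max_err, "u_identity_violations": u_identity_violations}


# ---------------------------------------------------------------------------
# granulometry recovery


def disk_peak_recovery(radii=range(3, 10)) -> dict:
    """Fraction of constructed binary-disk images whose peak equals the radius."""
    from skimage.morphology import disk as _disk

    exact = 0
    radii = list(radii)
    for r in radii:
        img = np.zeros((160, 160))
        d = _disk(r).astype(float)
        for cr, cc in [(40, 40), (40, 110), (110, 40), (110, 110)]:
            img[cr - r : cr + r + 1, cc - r : cc + r + 1] += d
        frame = Frame(img, fov_mask=np.ones_like(img, dtype=bool))
        prof = compute_granulometry(frame, 12)
        if prof.peak_radius == r:
            exact += 1
    return {"n": len(radii), "exact_fraction": exact / len(radii)}


def calibration_recovery(n_frames: int = 100, seed: int = 0) -> dict:
    """Per-frame granulometric radius recovery on simulated fields.

    Frames are generated at 256 x 256 with nominal cell radii cycling
    through 4, 5 and 6 px at the study cell rate and SNR; empty frames
    (no cells to size) are skipped and redrawn.  Reports the fraction of
    frames whose pattern-spectrum peak lies within one pixel of the
    nominal radius.
    """
    seeds = iter(_spawn(seed, 20 * n_frames))
    hits = 0
    for i in range(n_frames):
        nominal = (4, 5, 6)[i % 3]
        while True:
            cfg = SimulationConfig(
                frame_height=256, frame_width=256, n_frames=1,
                cell_radius_mean=float(nominal), cell_radius_sd=0.3,
                seed=next(seeds),
            )
            frame, truth = next(iter_video_frames(cfg))  # keeps the FOV mask
            if truth.true_count > 0:
                break
        enhanced = calibration_enhance(frame)
        peak = None
        if enhanced is not None:
            peak = compute_granulometry(enhanced, 10).peak_radius
        if peak is not None and abs(peak - nominal) <= 1:
            hits += 1
    return {"n": n_frames, "within_1px_fraction": hits / n_frames}


# ---------------------------------------------------------------------------
# detection accuracy and count recovery


def detection_benchmark(n_frames: int = 200, seed: int = 0) -> dict:
    """Precision/recall on default-geometry frames plus debris invariance.

    Runs the full per-frame pipeline on ``n_frames`` simulator frames at
    the default study conditions, scores detections against ground truth
    by one-to-one centroid matching within one cell radius, and then
    re-runs the identical cell/background realization without debris to
    check that debris changes no frame's count.
    """
    cfg = SimulationConfig(n_frames=n_frames, seed=seed)
    tp = fp = fn = 0
    counts_with_debris = []
    for frame, truth in iter_video_frames(cfg):
        det = count_frame(frame, DEFAULT_PARAMS)
        counts_with_debris.append(det.count)
        s = score_detections(det.objects, truth, MATCH_RADIUS)
        tp += s.true_positives
        fp += s.false_positives
        fn += s.false_negatives
    counts_without = [
        count_frame(frame, DEFAULT_PARAMS).count
        for frame, _ in iter_video_frames(replace(cfg, debris_rate=0.0))
    ]
    changed = sum(a != b for a, b in zip(counts_without, counts_with_debris))
    return {
        "n_frames": n_frames,
        "precision": tp / max(tp + fp, 1),
        "recall": tp / max(tp + fn, 1),
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "debris_changed_frames": changed,
    }


def count_recovery(seed: int = 0, n_frames: int = 240) -> dict:
    """Mean detected vs mean true count over one default-length video."""
    cfg = SimulationConfig(n_frames=n_frames, seed=seed)
    det_counts = []
    true_counts = []
    for frame, truth in iter_video_frames(cfg):
        det_counts.append(count_frame(frame, DEFAULT_PARAMS).count)
        true_counts.append(truth.true_count)
    mean_det = float(np.mean(det_counts))
    mean_true = float(np.mean(true_counts))
    ci_half = 2.576 * float(np.sqrt(max(mean_true, 1e-9) / n_frames))
    return {
        "n_frames": n_frames,
        "mean_detected": mean_det,
        "mean_true": mean_true,
        "ci99_half_width": ci_half,
        "within_ci": float(abs(mean_det - mean_true) <= ci_half),
    }


# ---------------------------------------------------------------------------
# study-level power and null behavior


def _study_p_value(rep_seed: int, rate_a: float, rate_b: float,
                   n_frames: int = 24) -> float:
    base = SimulationConfig(frame_height=128, frame_width=128, n_frames=n_frames,
                            seed=0)
    groups = [GroupSpec("Ctrl", "ET", rate_a, n_rats=5, videos_per_rat=2),
              GroupSpec("Ctrl", "IV", rate_b, n_rats=5, videos_per_rat=2)]
    study = generate_study(groups, base, seed=rep_seed)
    vqs = []
    for sv in study:
        dets = [count_frame(f, REDUCED_PARAMS) for f, _ in sv.frames()]
        vqs.append(quantify_video(dets, video_id=sv.video_id, rat_id=sv.rat_id,
                                  route=sv.route, condition=sv.condition))
    return compare_groups(vqs, factor="route", unit="rat", statistic="mean").p_value


def study_rejection_rate(n_reps: int, seed: int, rate_a: float = 3.6,
                         rate_b: float = 0.5, alpha: float = 0.05) -> dict:
    """Fraction of seeded replicate studies rejecting at ``alpha``.

    Each replicate simulates the full two-route design (5 rats per
    group, 2 videos per rat), counts every frame through the detection
    pipeline, aggregates per rat and applies the two-sided Mann-Whitney
    test.  With ``rate_a == rate_b`` this measures the empirical
    type-I error instead of power.
    """
    rejections = 0
    for rep_seed in _spawn(seed, n_reps):
        p = _study_p_value(rep_seed, rate_a, rate_b)
        rejections += p < alpha
    return {"n_replicates": n_reps, "rejection_fraction": rejections / n_reps}


# ---------------------------------------------------------------------------
# determinism


def pipeline_determinism(seed: int = 0) -> dict:
    """Byte-identity of a full simulate -> count -> compare file pipeline.

    Runs the pipeline twice into separate directories and compares the
    payload bytes of the video stack, the counts CSV and the comparison
    JSON.
    """

    def run_once(outdir: Path) -> None:
        base = SimulationConfig(frame_height=128, frame_width=128, n_frames=4, seed=0)
        groups = [GroupSpec("Ctrl", "ET", 3.6, n_rats=2, videos_per_rat=1),
                  GroupSpec("Ctrl", "IV", 0.5, n_rats=2, videos_per_rat=1)]
        study = generate_study(groups, base, seed=seed)
        vqs = []
        for sv in study:
            video, _ = generate_video(sv.config)
            write_video_tiff(video, outdir / f"{sv.video_id}.tif")
            dets = [count_frame(f, REDUCED_PARAMS) for f, _ in sv.frames()]
            write_counts_csv(dets, outdir / f"{sv.video_id}.csv")
            vqs.append(quantify_video(dets, video_id=sv.video_id, rat_id=sv.rat_id,
                                      route=sv.route, condition=sv.condition))
        res = compare_groups(vqs, factor="route", unit="video", statistic="mean")
        (outdir / "comparison.json").write_text(json.dumps({
            "u": res.u_statistic, "p": res.p_value,
            "a": list(res.group_a_values), "b": list(res.group_b_values),
        }, indent=2))

    with tempfile.TemporaryDirectory() as tmp:
        d1, d2 = Path(tmp) / "run1", Path(tmp) / "run2"
        d1.mkdir()
        d2.mkdir()
        run_once(d1)
        run_once(d2)
        identical = all(
            (d1 / f.name).read_bytes() == f.read_bytes()
            for f in sorted(d2.iterdir())
        )
    return {"identical": float(identical)}
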