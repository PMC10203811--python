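"""Synthetic cohorts, ratings and 4D rest/task images with known ground truth.

Every downstream stage (amplitude maps, first-level SME, group models, ROI
statistics) is testable against the injected truth without any external
data.  Determinism: a master seed plus a stable hash of the subject id
drives every per-subject random stream.

Calibration defaults follow the study cohort: 106 young / 111 older
subjects, scanner split 58/48 (young Verio/Skyra) and 64/47 (older),
recognition AUC 0.82 +/- 0.07 (young) and 0.77 +/- 0.07 (older), total
hippocampal volume 6890.91 +/- 638.65 mm^3 (young) and 6453.07 +/- 593.21
mm^3 (older), ages 24.12 +/- 4.00 in 18-35 and 67.28 +/- 4.65 in 60-80.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from restmem.amplitude import BoldSeries
from restmem.firstlevel import DesignMatrix, build_design
from restmem.roistats import RoiSet

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "GroundTruthManifest",
    "ImageGeometry",
    "EventSpec",
    "subject_rng",
    "generate_cohort",
    "cohort_frame",
    "calibrate_dprime",
    "expected_rating_auc",
    "generate_ratings",
    "generate_rest_bold",
    "generate_events",
    "generate_task_run",
    "generate_covariate_maps",
    "make_roi_set",
]

RATING_CRITERIA_SPACING = 1.0  # four equally spaced criteria, centered on d'/2


# ---------------------------------------------------------------------------
# specs and records


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort (defaults calibrated to the study)."""

    n_young: int = 106
    n_old: int = 111
    verio_frac_young: float = 58 / 106
    verio_frac_old: float = 64 / 111
    female_frac_young: float = 59 / 106
    female_frac_old: float = 65 / 111
    auc_mean_young: float = 0.82
    auc_mean_old: float = 0.77
    auc_sd: float = 0.07
    hc_mean_young: float = 6890.91
    hc_sd_young: float = 638.65
    hc_mean_old: float = 6453.07
    hc_sd_old: float = 593.21
    tiv_mean: float = 1_450_000.0
    tiv_sd: float = 140_000.0
    wmlv_logmean_young: float = np.log(300.0)
    wmlv_logsd_young: float = 0.8
    wmlv_logmean_old: float = np.log(2000.0)
    wmlv_logsd_old: float = 1.0
    age_range_young: tuple[float, float] = (18.0, 35.0)
    age_range_old: tuple[float, float] = (60.0, 80.0)
    age_mean_young: float = 24.12
    age_sd_young: float = 4.00
    age_mean_old: float = 67.28
    age_sd_old: float = 4.65
    rest_amp_mean_young: float = 2.0  # DMN amplitude, % of mean signal
    rest_amp_mean_old: float = 1.6
    rest_amp_sd: float = 0.25
    sme_beta_mean_young: float = -0.5  # signal units per PM unit in the DMN
    sme_beta_mean_old: float = -0.2
    sme_beta_sd: float = 0.1
    scanner_amp_factor: float = 1.0  # multiplicative Verio/Skyra amplitude effect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young <= 0 or self.n_old <= 0:
            raise ValueError("group sizes must be positive")
        for m in (self.auc_mean_young, self.auc_mean_old):
            if not 0.0 <= m <= 1.0:
                raise ValueError("AUC means must lie in [0, 1]")
        for sd in (self.auc_sd, self.hc_sd_young, self.hc_sd_old, self.tiv_sd,
                   self.age_sd_young, self.age_sd_old, self.rest_amp_sd,
                   self.sme_beta_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        y0, y1 = self.age_range_young
        o0, o1 = self.age_range_old
        if y0 >= y1 or o0 >= o1:
            raise ValueError("age ranges must be increasing intervals")
        if max(y0, o0) < min(y1, o1):
            raise ValueError("age ranges of the two groups overlap")


@dataclass
class SubjectRecord:
    subject_id: str
    age_group: str  # "young" | "older"
    scanner: str  # "Verio" | "Skyra"
    sex: str  # "m" | "f"
    age: float
    hc_vol: float
    tiv: float
    wmlv: float
    target_auc: float
    true_rest_amplitude_dmn: float  # % signal
    true_sme_beta_dmn: float  # signal units per PM unit

    def __post_init__(self) -> None:
        if min(self.hc_vol, self.tiv, self.wmlv) <= 0:
            raise ValueError("volumes must be positive")


@dataclass
class GroundTruthManifest:
    master_seed: int
    subjects: dict[str, dict]
    notes: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"master_seed": self.master_seed, "subjects": self.subjects,
                 "notes": self.notes},
                fh, indent=2, default=float,
            )


@dataclass
class ImageGeometry:
    """Desk-scale image grid (3 mm isotropic, RAS affine, grid-centered origin)."""

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 3.0
    tr: float = 2.58
    n_vols: int = 184

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.shape) - 1) / 2.0
        return aff

    @property
    def run_duration(self) -> float:
        return self.n_vols * self.tr


@dataclass
class EventSpec:
    n_novel: int = 88
    n_master: int = 44  # two master images, 22 presentations each
    duration: float = 2.5
    jitter: tuple[float, float] = (0.70, 2.65)
    lead_in: float = 6.0

    def __post_init__(self) -> None:
        if self.n_novel <= 0 or self.n_master < 0:
            raise ValueError("trial counts must be positive")
        if self.jitter[0] > self.jitter[1] or self.jitter[0] < 0:
            raise ValueError("invalid jitter bounds")


# ---------------------------------------------------------------------------
# seeding


def subject_rng(master_seed: int, subject_id: str, stream: str = "") -> np.random.Generator:
    """Generator derived by stable hashing of (master seed, subject id, stream)."""
    digest = hashlib.sha256(f"{master_seed}:{subject_id}:{stream}".encode()).digest()
    entropy = int.from_bytes(digest[:16], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# cohort generation


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _split_labels(n: int, frac: float, labels: tuple[str, str], rng) -> np.ndarray:
    n_first = int(round(frac * n))
    arr = np.array([labels[0]] * n_first + [labels[1]] * (n - n_first))
    rng.shuffle(arr)
    return arr


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], GroundTruthManifest]:
    """Draw a cohort of subject records plus the ground-truth manifest.

    Scanner and sex splits use exact (rounded) counts; continuous
    covariates are drawn per group (ages truncated to the group range,
    WMLV log-normal, volumes normal clipped positive).  Identical seeds
    yield identical cohorts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    subjects: list[SubjectRecord] = []
    truth: dict[str, dict] = {}

    groups = [
        ("young", spec.n_young, spec.verio_frac_young, spec.female_frac_young,
         spec.age_mean_young, spec.age_sd_young, spec.age_range_young,
         spec.hc_mean_young, spec.hc_sd_young,
         spec.wmlv_logmean_young, spec.wmlv_logsd_young,
         spec.auc_mean_young, spec.rest_amp_mean_young, spec.sme_beta_mean_young),
        ("older", spec.n_old, spec.verio_frac_old, spec.female_frac_old,
         spec.age_mean_old, spec.age_sd_old, spec.age_range_old,
         spec.hc_mean_old, spec.hc_sd_old,
         spec.wmlv_logmean_old, spec.wmlv_logsd_old,
         spec.auc_mean_old, spec.rest_amp_mean_old, spec.sme_beta_mean_old),
    ]
    for (label, n, verio_frac, female_frac, age_mean, age_sd, age_range,
         hc_mean, hc_sd, wmlv_mu, wmlv_sigma, auc_mean, amp_mean,
         sme_mean) in groups:
        scanner = _split_labels(n, verio_frac, ("Verio", "Skyra"), rng)
        sex = _split_labels(n, female_frac, ("f", "m"), rng)
        age = _truncated_normal(rng, age_mean, age_sd, *age_range, size=n)
        hc = np.clip(rng.normal(hc_mean, hc_sd, size=n), 1.0, None)
        tiv = np.clip(rng.normal(spec.tiv_mean, spec.tiv_sd, size=n), 1.0, None)
        wmlv = np.exp(rng.normal(wmlv_mu, wmlv_sigma, size=n))
        target_auc = np.clip(rng.normal(auc_mean, spec.auc_sd, size=n), 0.505, 0.995)
        amp = np.clip(rng.normal(amp_mean, spec.rest_amp_sd, size=n), 0.05, None)
        sme = rng.normal(sme_mean, spec.sme_beta_sd, size=n)
        for i in range(n):
            sid = f"sub-{label[0].upper()}{i + 1:03d}"
            rec = SubjectRecord(
                subject_id=sid,
                age_group=label,
                scanner=str(scanner[i]),
                sex=str(sex[i]),
                age=float(age[i]),
                hc_vol=float(hc[i]),
                tiv=float(tiv[i]),
                wmlv=float(wmlv[i]),
                target_auc=float(target_auc[i]),
                true_rest_amplitude_dmn=float(amp[i]),
                true_sme_beta_dmn=float(sme[i]),
            )
            subjects.append(rec)
            truth[sid] = {
                "target_auc": rec.target_auc,
                "true_rest_amplitude_dmn": rec.true_rest_amplitude_dmn,
                "true_sme_beta_dmn": rec.true_sme_beta_dmn,
            }
    manifest = GroundTruthManifest(
        master_seed=spec.seed,
        subjects=truth,
        notes={"spec": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(spec).items()}},
    )
    return subjects, manifest


def cohort_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in subjects])


# ---------------------------------------------------------------------------
# ratings (equal-variance Gaussian signal detection)


def _criteria(dprime: float) -> np.ndarray:
    offsets = (np.arange(4) - 1.5) * RATING_CRITERIA_SPACING
    return dprime / 2.0 + offsets


def expected_rating_auc(dprime: float) -> float:
    """Expected trapezoidal AUC of the binned 5-point rating ROC.

    New-item strengths are N(0,1), old items N(d', 1); four equally spaced
    criteria centered on d'/2 bin strengths into ratings 1-5.  Because hit
    and false-alarm proportions come from independent samples, the
    empirical trapezoidal AUC is an unbiased estimator of this value.
    """
    c = _criteria(dprime)
    fa = np.concatenate([[0.0], stats.norm.sf(c)[::-1], [1.0]])
    hits = np.concatenate([[0.0], stats.norm.sf(c - dprime)[::-1], [1.0]])
    return float(np.trapezoid(hits, fa))


def calibrate_dprime(target_auc: float) -> float:
    """Separation d' whose expected binned-ROC AUC equals ``target_auc``."""
    if not 0.5 <= target_auc < 1.0:
        raise ValueError(f"target AUC must be in [0.5, 1), got {target_auc}")
    if target_auc == 0.5:
        return 0.0
    return float(optimize.brentq(lambda d: expected_rating_auc(d) - target_auc, 0.0, 10.0))


def generate_ratings(
    subject: SubjectRecord | float,
    n_old_items: int = 88,
    n_new_items: int = 44,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Rating table (item_id, status, rating) from the calibrated SDT model.

    ``subject`` may be a SubjectRecord (uses its target AUC and a
    seed derived from its id when ``seed`` is None) or a bare target AUC.
    """
    if n_old_items <= 0 or n_new_items <= 0:
        raise ValueError("item counts must be positive")
    if isinstance(subject, SubjectRecord):
        target = subject.target_auc
        if seed is None:
            rng = subject_rng(0, subject.subject_id, "ratings")
        elif isinstance(seed, np.random.Generator):
            rng = seed
        else:
            rng = subject_rng(int(seed), subject.subject_id, "ratings")
    else:
        target = float(subject)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = calibrate_dprime(target)
    crit = _criteria(d)
    old_strength = rng.normal(d, 1.0, size=n_old_items)
    new_strength = rng.normal(0.0, 1.0, size=n_new_items)
    ratings = np.concatenate([
        np.searchsorted(crit, old_strength) + 1,
        np.searchsorted(crit, new_strength) + 1,
    ])
    status = ["old"] * n_old_items + ["new"] * n_new_items
    ids = [f"old-{i + 1:03d}" for i in range(n_old_items)] + [
        f"new-{i + 1:03d}" for i in range(n_new_items)
    ]
    return pd.DataFrame({"item_id": ids, "status": status, "rating": ratings.astype(int)})


# ---------------------------------------------------------------------------
# rest BOLD


def _band_limited_noise(rng, n_series: int, n_vols: int, tr: float,
                        band: tuple[float, float]) -> np.ndarray:
    """Unit-SD series that are exactly band-limited (random phases, flat
    in-band power), shape (n_series, n_vols)."""
    freqs = np.fft.rfftfreq(n_vols, d=tr)
    in_band = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not in_band.any():
        raise ValueError(f"no FFT bins inside band {band} at tr={tr}, n={n_vols}")
    spec = np.zeros((n_series, freqs.size), dtype=complex)
    phases = rng.uniform(0, 2 * np.pi, size=(n_series, int(in_band.sum())))
    spec[:, in_band] = np.exp(1j * phases)
    series = np.fft.irfft(spec, n=n_vols, axis=-1)
    sd = series.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return series / sd


def generate_rest_bold(
    subject: SubjectRecord,
    geometry: ImageGeometry,
    dmn_mask: np.ndarray,
    seed: int | None = None,
    band: tuple[float, float] = (0.01, 0.08),
    baseline: float = 1000.0,
    background_amplitude: float = 1.0,
    white_noise_sd: float = 0.0,
    amplitude_scale: float = 1.0,
) -> BoldSeries:
    """Rest run: baseline + band-limited fluctuations + white noise.

    Inside ``dmn_mask`` the fluctuation is scaled so that its percent
    amplitude (mean absolute deviation relative to baseline, x100) equals
    ``subject.true_rest_amplitude_dmn * amplitude_scale``; elsewhere it is
    ``background_amplitude``.  For Gaussian fluctuations the expected mean
    absolute deviation is sd * sqrt(2/pi), which fixes the scaling.
    """
    dmn_mask = np.asarray(dmn_mask, dtype=bool)
    if dmn_mask.shape != tuple(geometry.shape):
        raise ValueError("dmn_mask shape does not match geometry")
    if not dmn_mask.any():
        raise ValueError("dmn_mask is empty")
    if seed is None:
        rng = subject_rng(0, subject.subject_id, "rest")
    else:
        rng = np.random.default_rng(seed)

    n_vox = int(np.prod(geometry.shape))
    amp = np.full(n_vox, background_amplitude, dtype=float)
    amp[dmn_mask.reshape(-1)] = subject.true_rest_amplitude_dmn * amplitude_scale
    sigma = amp * baseline * np.sqrt(np.pi / 2.0) / 100.0

    data = np.full((n_vox, geometry.n_vols), baseline, dtype=float)
    active = sigma > 0
    if active.any():
        fluct = _band_limited_noise(rng, int(active.sum()), geometry.n_vols,
                                    geometry.tr, band)
        data[active] += fluct * sigma[active, None]
    if white_noise_sd > 0:
        data += rng.normal(0.0, white_noise_sd, size=data.shape)
    return BoldSeries(
        data=data.reshape(*geometry.shape, geometry.n_vols),
        tr=geometry.tr,
        affine=geometry.affine,
    )


# ---------------------------------------------------------------------------
# task BOLD


def generate_events(
    event_spec: EventSpec,
    rng: np.random.Generator,
    ratings: np.ndarray | None = None,
) -> pd.DataFrame:
    """Jittered event table (onset, duration, trial_type, rating).

    Novel and master trials are interleaved in random order; each trial is
    a jittered fixation (uniform within the jitter bounds) followed by the
    stimulus.  ``ratings`` supplies the subsequent-memory rating of each
    novel trial (NaN for master trials in the output).
    """
    n_total = event_spec.n_novel + event_spec.n_master
    kinds = np.array(["novel"] * event_spec.n_novel + ["master"] * event_spec.n_master)
    rng.shuffle(kinds)
    jitters = rng.uniform(*event_spec.jitter, size=n_total)
    onsets = event_spec.lead_in + np.cumsum(jitters) + \
        np.arange(n_total) * event_spec.duration
    rating_col = np.full(n_total, np.nan)
    if ratings is not None:
        ratings = np.asarray(ratings)
        if ratings.size != event_spec.n_novel:
            raise ValueError("need one rating per novel trial")
        rating_col[kinds == "novel"] = ratings
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(n_total, event_spec.duration),
            "trial_type": kinds,
            "rating": rating_col,
        }
    )


def generate_task_run(
    subject: SubjectRecord,
    geometry: ImageGeometry,
    event_spec: EventSpec | None = None,
    seed: int | None = None,
    sme_mask: np.ndarray | None = None,
    novelty_beta: float = 1.0,
    master_beta: float = 0.5,
    baseline: float = 1000.0,
    noise_sd: float = 0.0,
) -> tuple[BoldSeries, pd.DataFrame]:
    """Task run whose SME voxels scale with the subject's true SME beta.

    The BOLD signal is the first-level design (novelty + master boxcars
    convolved with the HRF, plus the PM-modulated novelty regressor) times
    voxel-wise true betas, plus optional white noise.  Novel-trial ratings
    are drawn from the subject's calibrated signal-detection model (they
    are the "old" items of the later recognition test).  Raises if the run
    is too short for the requested trials.
    """
    event_spec = event_spec or EventSpec()
    if seed is None:
        rng = subject_rng(0, subject.subject_id, "task")
    else:
        rng = np.random.default_rng(seed)
    if sme_mask is None:
        sme_mask = np.zeros(geometry.shape, dtype=bool)
    sme_mask = np.asarray(sme_mask, dtype=bool)
    if sme_mask.shape != tuple(geometry.shape):
        raise ValueError("sme_mask shape does not match geometry")

    rating_table = generate_ratings(subject, n_old_items=event_spec.n_novel,
                                    n_new_items=1, seed=rng)
    novel_ratings = rating_table.loc[rating_table["status"] == "old", "rating"].to_numpy()
    events = generate_events(event_spec, rng, ratings=novel_ratings)
    end = (events["onset"] + events["duration"]).max()
    if end > geometry.run_duration:
        raise ValueError(
            f"run too short for requested trials: events end at {end:.1f} s, "
            f"run lasts {geometry.run_duration:.1f} s"
        )
    design = build_design(events, n_scans=geometry.n_vols, tr=geometry.tr)

    n_vox = int(np.prod(geometry.shape))
    betas = np.zeros((len(design.names), n_vox))
    betas[design.names.index("novelty")] = novelty_beta
    if "master" in design.names:
        betas[design.names.index("master")] = master_beta
    if "novelty_x_pm" in design.names:
        sme_row = np.zeros(n_vox)
        sme_row[sme_mask.reshape(-1)] = subject.true_sme_beta_dmn
        betas[design.names.index("novelty_x_pm")] = sme_row
    betas[design.names.index("constant")] = baseline

    data = (design.values @ betas).T
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    bold = BoldSeries(
        data=data.reshape(*geometry.shape, geometry.n_vols),
        tr=geometry.tr,
        affine=geometry.affine,
    )
    return bold, events


# ---------------------------------------------------------------------------
# covariate maps and geometric ROI stand-ins


def _box(shape, lo, hi) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


def make_roi_set(geometry: ImageGeometry) -> RoiSet:
    """Geometric stand-ins for the DMN ROI set.

    Disjoint midline boxes for mPFC/ACC (anterior), PCC and precuneus
    (posterior), plus their union as the composite DMN.  Box positions
    scale with the grid.
    """
    nx, ny, nz = geometry.shape

    def span(n, lo_frac, hi_frac):
        lo = int(np.floor(lo_frac * n))
        hi = max(int(np.ceil(hi_frac * n)), lo + 1)
        return lo, min(hi, n)

    x0, x1 = span(nx, 0.4, 0.6)  # midline slab
    z0, z1 = span(nz, 0.4, 0.6)
    ya0, ya1 = span(ny, 0.75, 1.00)  # anterior (mPFC/ACC)
    yp0, yp1 = span(ny, 0.10, 0.25)  # posterior (PCC)
    ym0, ym1 = span(ny, 0.30, 0.50)  # superior-posterior (precuneus)
    mpfc = _box(geometry.shape, (x0, ya0, z0), (x1, ya1, z1))
    pcc = _box(geometry.shape, (x0, yp0, z0), (x1, yp1, z1))
    precuneus = _box(geometry.shape, (x0, ym0, z0), (x1, ym1, z1))
    precuneus &= ~pcc
    dmn = mpfc | pcc | precuneus
    return RoiSet(
        {"dmn": dmn, "mpfc_acc": mpfc, "pcc": pcc, "precuneus": precuneus},
        affine=geometry.affine,
    )


def generate_covariate_maps(
    cohort: list[SubjectRecord],
    geometry: ImageGeometry,
    seed: int = 0,
    base_gmv: float = 600.0,
    subject_sd: float = 40.0,
    smooth_sigma: float = 1.5,
    group_effect: float = 0.0,
    effect_region: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], RoiSet]:
    """Smooth positive per-subject GMV maps plus the geometric ROI set.

    ``group_effect`` (added to older subjects inside ``effect_region``)
    defaults to 0, i.e. no between-group GMV difference.
    """
    rois = make_roi_set(geometry)
    if effect_region is None:
        effect_region = rois["dmn"]
    maps: dict[str, np.ndarray] = {}
    for subj in cohort:
        rng = subject_rng(seed, subj.subject_id, "gmv")
        noise = rng.normal(0.0, 1.0, size=geometry.shape)
        smooth = ndimage.gaussian_filter(noise, smooth_sigma)
        smooth *= subject_sd / max(smooth.std(), np.finfo(float).tiny)
        gmv = base_gmv + smooth
        if group_effect and subj.age_group == "older":
            gmv = gmv + group_effect * effect_region
        maps[subj.subject_id] = np.clip(gmv, 1.0, None)
    return maps, rois
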