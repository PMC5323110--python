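"""Synthetic resting-state cohorts with known ground truth.

Generates everything a downstream analysis needs -- 4D BOLD volumes,
tissue masks, gray-matter probability maps, motion traces, and a
phenotype table -- from an explicit generative model, so that every
pipeline stage has a recoverable target:

* each functional region carries a band-limited (0.01-0.08 Hz) regional
  signal; voxels inside a region share it, which is what regional
  homogeneity detects, and a per-group gain plants ReHo group
  differences in the two seed regions;
* target regions mix their seed's latent signal with a subject-specific
  coupling (Fisher-z scale), so seed-based correlation maps recover the
  planted coupling; group coupling differs per group (raised in
  patients for the frontal network's MCC-like target, lowered for the
  retrosplenial network's PCC/precuneus-like target);
* neuropsychological scores follow a mediation model: executive
  function EF differs by group (timed scores: higher = worse), the
  planted seed->MCC coupling is the mediator M = z_group + a*(EF - EF
  group mean) + noise, and episodic memory EM = intercept_group + c'*EF
  + b*M + noise.  Group intercepts and residual SDs are solved
  analytically so the cohort reproduces the calibration composite means
  and SDs (patients EM low / EF high).

BOLD volumes are generated per subject on demand (`Cohort.bold(i)`)
from a per-subject seed, so large cohorts never hold all images in
memory while remaining byte-reproducible for a fixed top-level seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import NETWORKS, SEED_REGIONS, AtlasSpec, default_atlas
from .core import BoldSeries, MotionTrace
from . import io as rio

log = logging.getLogger(__name__)

BAND_HZ = (0.01, 0.08)

#: raw-score scales (pooled mean, pooled SD) for the six tests; delayed
#: recall counts for the memory tests, completion seconds for the timed ones
RAW_SCALES = {
    "AVLT_DR": (6.0, 2.5),
    "CFT_DR": (14.0, 6.0),
    "LMT_DR": (8.0, 4.0),
    "TMT_A": (65.0, 25.0),
    "TMT_B": (160.0, 60.0),
    "SCWT_C": (85.0, 30.0),
}
EM_TESTS = ("AVLT_DR", "CFT_DR", "LMT_DR")
EF_TESTS = ("TMT_A", "TMT_B", "SCWT_C")

MIN_REGION_VOXELS = 8


@dataclass
class GroundTruth:
    """Generative parameters for a synthetic cohort.

    ``group_coupling`` maps group -> target region -> coupling on the
    Fisher-z scale; ``mediation`` holds (a, b, c_prime); the calibration
    fields are the per-group composite means/SDs the phenotypes are
    solved to reproduce.
    """

    group_coupling: dict = field(default_factory=dict)
    coupling_subject_sd: float = 0.10
    # mediation generative parameters: M = z_MCC + a*(EF - EF_mean) + e2
    a: float = 0.30
    b: float = -0.50
    c_prime: float = -0.20
    mediator_noise_sd: float = 0.30
    # calibration targets (composite z-score scale)
    ef_group_mean: dict = field(default_factory=lambda: {"patient": 0.44, "control": -0.27})
    ef_group_sd: dict = field(default_factory=lambda: {"patient": 0.95, "control": 0.52})
    em_group_mean: dict = field(default_factory=lambda: {"patient": -0.74, "control": 0.50})
    em_group_sd: dict = field(default_factory=lambda: {"patient": 0.71, "control": 0.51})
    # image-level parameters.  ReHo hotspots are planted as per-group
    # *local-noise multipliers*: lower local noise means higher local
    # homogeneity, while the regional signal amplitude (hence seed-based
    # connectivity and the global mean) stays group-invariant.
    reho_hotspots: dict = field(default_factory=dict)  # region -> group -> noise mult
    default_region_gain: float = 1.0
    voxel_noise_sd: float = 0.6
    #: fraction of voxel-noise variance carried by a spatially smooth
    #: component (intrinsic spatial autocorrelation of BOLD noise)
    spatial_noise_frac: float = 0.5
    spatial_noise_sigma_vox: float = 1.2
    #: multiplicative between-subject jitter (SD of log-gain) applied to
    #: regional signal amplitudes and the global fluctuation
    subject_amp_jitter_sd: float = 0.2
    global_amp: float = 0.2
    baseline: float = 100.0
    atrophy_effect: float = 0.0
    atrophy_regions: tuple = SEED_REGIONS

    @property
    def c_total(self) -> float:
        """Total EF -> EM effect implied by the generative model."""
        return self.c_prime + self.a * self.b

    @property
    def indirect_ratio(self) -> float:
        if self.c_total == 0:
            return float("nan")
        return (self.a * self.b) / self.c_total

    def coupling(self, group: str, target: str) -> float:
        return self.group_coupling.get(group, {}).get(target, 0.0)

    def region_gain(self, region: str, group: str) -> float:
        return self.default_region_gain

    def local_noise_mult(self, region: str, group: str) -> float:
        return self.reho_hotspots.get(region, {}).get(group, 1.0)

    def em_intercept(self, group: str) -> float:
        """Group EM intercept solving the calibration mean."""
        z_mcc = self.coupling(group, "target_MCC")
        return (self.em_group_mean[group]
                - self.c_prime * self.ef_group_mean[group]
                - self.b * z_mcc)

    def em_noise_sd(self, group: str) -> float:
        """Residual EM SD solving the calibration group SD."""
        explained = (self.c_total ** 2 * self.ef_group_sd[group] ** 2
                     + self.b ** 2 * self.mediator_noise_sd ** 2)
        var = self.em_group_sd[group] ** 2 - explained
        if var <= 0:
            raise ValueError(
                "EM calibration SD smaller than the variance explained by "
                "the mediation paths; reduce |c|, |b|, or the EF SD")
        return float(np.sqrt(var))


def default_truth() -> GroundTruth:
    """Calibrated defaults: the conditions the cohort emulates."""
    return GroundTruth(
        group_coupling={
            # frontal (DLPFC-like) network: raised coupling in patients
            "patient": {"target_MCC": 0.40, "target_caudate": 0.40,
                        "target_ACG_SMA": 0.40, "target_IPL_L": 0.30,
                        # retrosplenial network: lowered in patients
                        "target_PCC_PCu": 0.10, "target_IPL_R": 0.30},
            "control": {"target_MCC": 0.10, "target_caudate": 0.10,
                        "target_ACG_SMA": 0.10, "target_IPL_L": 0.30,
                        "target_PCC_PCu": 0.40, "target_IPL_R": 0.30},
        },
        # local homogeneity raised in patients: less local noise in the
        # seed regions (multipliers keep the contrast on the steep part
        # of the noise->W curve instead of the saturated top)
        reho_hotspots={
            "seed_DLPFC": {"patient": 0.6, "control": 2.2},
            "seed_RSC": {"patient": 0.6, "control": 2.2},
        },
    )


def null_truth() -> GroundTruth:
    """No planted couplings, effects, or group differences."""
    return GroundTruth(
        group_coupling={},
        a=0.0, b=0.0, c_prime=0.0,
        ef_group_mean={"patient": 0.0, "control": 0.0},
        ef_group_sd={"patient": 1.0, "control": 1.0},
        em_group_mean={"patient": 0.0, "control": 0.0},
        em_group_sd={"patient": 1.0, "control": 1.0},
        reho_hotspots={},
    )


@dataclass
class SubjectRecord:
    """Ground-truth state for one simulated subject."""

    subject_id: str
    group: str
    age: int
    gender: int
    education: int
    couplings: dict  # target region -> subject Fisher-z coupling
    ef_true: float
    em_true: float
    mediator_true: float  # planted seed->MCC coupling (z scale)
    raw_scores: dict
    bold_seed: int
    motion_seed: int
    gm_seed: int


def bandlimited_noise(rng: np.random.Generator, n: int, tr_s: float,
                      low_hz: float = BAND_HZ[0],
                      high_hz: float = BAND_HZ[1]) -> np.ndarray:
    """Unit-variance noise with power confined to [low_hz, high_hz]."""
    if high_hz >= 0.5 / tr_s:
        raise ValueError(
            f"band edge {high_hz} Hz not representable at TR {tr_s}s "
            f"(Nyquist {0.5 / tr_s:.4f} Hz)")
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=tr_s)
    spec[(freqs < low_hz) | (freqs > high_hz)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("band contains no FFT bins at this length/TR")
    return x / sd


def generate_motion(n_volumes: int, spike_times=(), spike_mm: float = 0.0,
                    seed: int = 0, walk_step_sd: float = 0.01) -> MotionTrace:
    """Smooth low-amplitude random-walk motion with optional spikes.

    Each spike is a persistent offset of ``spike_mm`` on every
    translation axis beginning at the given volume (a net displacement),
    so a single spike produces exactly one suprathreshold transition
    with framewise RMS spike_mm/sqrt(2) under the six-parameter RMS
    convention.
    """
    spike_times = tuple(int(s) for s in spike_times)
    if any(s < 0 or s >= n_volumes for s in spike_times):
        raise ValueError("spike index out of range")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes, 6)) * walk_step_sd
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    for s in spike_times:
        params[s:, :3] += spike_mm
    return MotionTrace(params)


def generate_gm_map(atlas: AtlasSpec, atrophy_effect: float = 0.0,
                    group: str = "control", seed: int = 0,
                    atrophy_regions=SEED_REGIONS) -> np.ndarray:
    """Smooth GM probability map, strictly inside (0, 1).

    Patients lose ``atrophy_effect`` of GM probability in the designated
    regions (seed regions by default).
    """
    if atrophy_effect < 0:
        raise ValueError("atrophy_effect must be nonnegative")
    rng = np.random.default_rng(seed)
    base = np.full(atlas.grid_shape, 0.05)
    base[atlas.brain_mask] = 0.35
    base[atlas.gm_mask] = 0.75
    base[atlas.regions["wm"]] = 0.25
    base[atlas.regions["csf"]] = 0.10
    if group == "patient" and atrophy_effect > 0:
        for name in atrophy_regions:
            base[atlas.regions[name]] -= atrophy_effect
    noise = ndimage.gaussian_filter(rng.standard_normal(atlas.grid_shape), 1.5)
    gm = base + 0.25 * noise
    gm = ndimage.gaussian_filter(gm, 0.8)
    return np.clip(gm, 0.01, 0.99)


def generate_bold(subject: SubjectRecord, atlas: AtlasSpec,
                  truth: GroundTruth, n_volumes: int = 240,
                  tr_s: float = 2.0, seed: int | None = None) -> BoldSeries:
    """One subject's 4D BOLD volume from the planted generative model."""
    if n_volumes < 50:
        raise ValueError("need at least 50 volumes")
    if 0.5 / tr_s <= BAND_HZ[1]:
        raise ValueError(
            f"TR {tr_s}s cannot represent the {BAND_HZ[1]} Hz band edge")
    _check_atlas_capacity(atlas)
    rng = np.random.default_rng(subject.bold_seed if seed is None else seed)

    latents = {name: bandlimited_noise(rng, n_volumes, tr_s)
               for name in SEED_REGIONS}
    # voxel noise: white plus a spatially smooth component, reproducing the
    # intrinsic spatial autocorrelation of BOLD noise
    frac = float(np.clip(truth.spatial_noise_frac, 0.0, 1.0))
    data = rng.standard_normal(atlas.grid_shape + (n_volumes,))
    if frac > 0:
        smooth = ndimage.gaussian_filter(
            rng.standard_normal(atlas.grid_shape + (n_volumes,)),
            sigma=(truth.spatial_noise_sigma_vox,) * 3 + (0.0,))
        smooth /= smooth.std()
        data = np.sqrt(1 - frac) * data + np.sqrt(frac) * smooth
    data *= truth.voxel_noise_sd

    def jitter() -> float:
        return float(np.exp(rng.normal(0.0, truth.subject_amp_jitter_sd)))

    # ReHo hotspots: rescale local noise before signals are layered in
    for region, by_group in truth.reho_hotspots.items():
        mult = truth.local_noise_mult(region, subject.group) * jitter()
        data[atlas.regions[region]] *= mult

    data[atlas.brain_mask] += truth.baseline
    data[atlas.brain_mask] += (truth.global_amp * jitter()
                               * bandlimited_noise(rng, n_volumes, tr_s))
    for tissue in ("wm", "csf"):
        data[atlas.regions[tissue]] += jitter() * bandlimited_noise(rng, n_volumes, tr_s)

    for seed_name in SEED_REGIONS:
        gain = truth.region_gain(seed_name, subject.group) * jitter()
        data[atlas.regions[seed_name]] += gain * latents[seed_name]
        for target in NETWORKS[seed_name]:
            z = subject.couplings.get(target, 0.0)
            r = float(np.tanh(z))
            own = bandlimited_noise(rng, n_volumes, tr_s)
            signal = r * latents[seed_name] + np.sqrt(max(0.0, 1 - r * r)) * own
            g = truth.region_gain(target, subject.group) * jitter()
            data[atlas.regions[target]] += g * signal

    return BoldSeries(data=data, affine=atlas.affine, tr_s=tr_s,
                      voxel_size_mm=atlas.voxel_size_mm,
                      mask=atlas.brain_mask)


def _check_atlas_capacity(atlas: AtlasSpec) -> None:
    for name, m in atlas.regions.items():
        if m.sum() < MIN_REGION_VOXELS:
            raise ValueError(
                f"atlas region {name!r} has {int(m.sum())} voxels; "
                f"need >= {MIN_REGION_VOXELS} to host the planted effects")


@dataclass
class Cohort:
    """A generated cohort: phenotypes plus on-demand per-subject images."""

    atlas: AtlasSpec
    truth: GroundTruth
    subjects: list
    motions: list
    gm_maps: list
    phenotypes: pd.DataFrame
    n_volumes: int
    tr_s: float
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def bold(self, i: int) -> BoldSeries:
        """Generate subject i's BOLD series (deterministic per seed)."""
        return generate_bold(self.subjects[i], self.atlas, self.truth,
                             n_volumes=self.n_volumes, tr_s=self.tr_s)

    def groups(self) -> np.ndarray:
        return self.phenotypes["group"].to_numpy()


def _subject_seed(seed: int, i: int, stream: int) -> int:
    return int((seed * 1_000_003 + i * 97 + stream * 11) % (2 ** 31 - 1))


def _member_noise_sd(truth: GroundTruth, domain_means, domain_sds,
                     n_p: int, n_c: int) -> float:
    """Per-test noise solving pooled member variance ~ 1, so pooled
    z-scoring downstream preserves the calibration group means."""
    w = np.array([n_p, n_c]) / (n_p + n_c)
    means = np.array([domain_means["patient"], domain_means["control"]])
    sds = np.array([domain_sds["patient"], domain_sds["control"]])
    pooled_mean = float(w @ means)
    pooled_var = float(w @ (sds ** 2 + (means - pooled_mean) ** 2))
    return float(np.sqrt(max(1.0 - pooled_var, 0.01)))


def generate_cohort(n_patient: int, n_control: int,
                    atlas: AtlasSpec | None = None,
                    truth: GroundTruth | None = None,
                    seed: int = 0, n_volumes: int = 240,
                    tr_s: float = 2.0, spike_prob: float = 0.3,
                    images: bool = True) -> Cohort:
    """Generate a full cohort (phenotypes, motion, GM; BOLD on demand).

    ``images=False`` skips motion traces and GM maps for phenotype-only
    studies (e.g. repeated mediation cohorts); the phenotype stream is
    identical either way.
    """
    if n_patient < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group")
    atlas = atlas or default_atlas()
    truth = truth or default_truth()
    _check_atlas_capacity(atlas)
    # fail early if the calibration is infeasible
    for g in ("patient", "control"):
        truth.em_noise_sd(g)

    rng = np.random.default_rng(seed)
    s_em = _member_noise_sd(truth, truth.em_group_mean, truth.em_group_sd,
                            n_patient, n_control)
    s_ef = _member_noise_sd(truth, truth.ef_group_mean, truth.ef_group_sd,
                            n_patient, n_control)

    subjects, motions, gm_maps, rows = [], [], [], []
    groups = ["patient"] * n_patient + ["control"] * n_control
    for i, group in enumerate(groups):
        age = int(rng.integers(54, 81))
        gender = int(rng.integers(0, 2))
        education = int(rng.integers(6, 21))

        ef = float(rng.normal(truth.ef_group_mean[group],
                              truth.ef_group_sd[group]))
        ef_centered = ef - truth.ef_group_mean[group]
        mediator = (truth.coupling(group, "target_MCC")
                    + truth.a * ef_centered
                    + float(rng.normal(0.0, truth.mediator_noise_sd)))
        em = (truth.em_intercept(group) + truth.c_prime * ef
              + truth.b * mediator
              + float(rng.normal(0.0, truth.em_noise_sd(group))))

        couplings = {}
        for seed_name, targets in NETWORKS.items():
            for target in targets:
                if target == "target_MCC":
                    couplings[target] = mediator
                else:
                    couplings[target] = (truth.coupling(group, target)
                                         + float(rng.normal(0.0, truth.coupling_subject_sd)))

        raw = {}
        for test in EM_TESTS:
            mu, sd = RAW_SCALES[test]
            raw[test] = mu + sd * (em + float(rng.normal(0.0, s_em)))
        for test in EF_TESTS:
            mu, sd = RAW_SCALES[test]
            raw[test] = mu + sd * (ef + float(rng.normal(0.0, s_ef)))

        n_spikes = int(rng.random() < spike_prob)
        spike_times = (tuple(rng.integers(20, n_volumes - 10, size=n_spikes))
                       if n_spikes else ())
        # dRMS of a spike is spike_mm/sqrt(2): 0.8-1.4 mm all trip the
        # 0.5 mm rule while staying well inside the 2.0 mm exclusion bound
        spike_mm = float(rng.uniform(0.8, 1.4)) if n_spikes else 0.0

        rec = SubjectRecord(
            subject_id=f"sub-{i + 1:03d}", group=group, age=age,
            gender=gender, education=education, couplings=couplings,
            ef_true=ef, em_true=em, mediator_true=mediator, raw_scores=raw,
            bold_seed=_subject_seed(seed, i, 1),
            motion_seed=_subject_seed(seed, i, 2),
            gm_seed=_subject_seed(seed, i, 3),
        )
        subjects.append(rec)
        if images:
            motions.append(generate_motion(n_volumes, spike_times, spike_mm,
                                           seed=rec.motion_seed))
            gm_maps.append(generate_gm_map(atlas, truth.atrophy_effect, group,
                                           seed=rec.gm_seed))
        rows.append({"subject_id": rec.subject_id, "group": group,
                     "age": age, "gender": gender, "education": education,
                     **raw})

    phenotypes = pd.DataFrame(rows)
    return Cohort(atlas=atlas, truth=truth, subjects=subjects,
                  motions=motions, gm_maps=gm_maps, phenotypes=phenotypes,
                  n_volumes=n_volumes, tr_s=tr_s, seed=seed)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort's file interface: NIfTI volumes, TSVs, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = cohort.atlas
    rio.save_nifti(outdir / "brain_mask.nii.gz", atlas.brain_mask, atlas.affine)
    rio.save_nifti(outdir / "wm_mask.nii.gz", atlas.regions["wm"], atlas.affine)
    rio.save_nifti(outdir / "csf_mask.nii.gz", atlas.regions["csf"], atlas.affine)
    rio.save_nifti(outdir / "region_labels.nii.gz", atlas.label_volume(), atlas.affine)
    rio.save_phenotypes_tsv(outdir / "phenotypes.tsv", cohort.phenotypes)
    truth = cohort.truth
    rio.save_json(outdir / "ground_truth.json", {
        "group_coupling": truth.group_coupling,
        "mediation": {"a": truth.a, "b": truth.b, "c_prime": truth.c_prime,
                      "c_total": truth.c_total,
                      "indirect_ratio": truth.indirect_ratio
                      if np.isfinite(truth.indirect_ratio) else None},
        "reho_hotspots": truth.reho_hotspots,
        "seed": cohort.seed,
    })
    for i, rec in enumerate(cohort.subjects):
        sid = rec.subject_id
        rio.save_bold(outdir / f"{sid}_bold.nii.gz", cohort.bold(i))
        rio.save_motion_tsv(outdir / f"{sid}_motion.tsv", cohort.motions[i])
        rio.save_nifti(outdir / f"{sid}_gm.nii.gz", cohort.gm_maps[i], atlas.affine)
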