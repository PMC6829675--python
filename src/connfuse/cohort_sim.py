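"""Synthetic cohort generator for the two-group connectivity analysis.

Emulates the statistical structure the downstream pipeline assumes: a
patient group (+1) and a control group (-1), a 90-region parcellation,
per-subject ROI time series whose planted anterior-midline edges have
configured group means/SDs on the Fisher-z scale, group-level structural
covariance among regional gray-matter volumes, episode sublabels shifting
the planted-edge summation score, demographic covariate confounding, and
realistic motion traces with optional spikes for QC testing.

Construction of the time series (only second-order structure matters
downstream): for each subject a target correlation matrix is assembled
from a common background level plus per-subject planted-edge correlations
``tanh(z)``, where ``z`` is drawn per subject around the group mean; the
matrix is projected to the nearest positive-definite correlation matrix by
eigenvalue clipping and T i.i.d. Gaussian frames are drawn from it.  The
latent between-subject SD is deflated by the finite-T sampling variance
``1/(T-3)`` so the *measured* Fisher-z values have the configured SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .connectome import EdgeIndex

# AAL 1-based indices of the anterior-midline regions of interest
ACC_L, ACC_R = 31, 32
SMPFC_L, SMPFC_R = 23, 24

#: Default planted functional edges (1-based regions, mean_z patients,
#: mean_z controls, between-subject SD): the four ACC--sMPFC connections.
DEFAULT_PLANTED_EDGES: tuple[tuple[int, int, float, float, float], ...] = (
    (ACC_L, SMPFC_L, -0.10, 0.09, 0.235),
    (ACC_R, SMPFC_L, -0.09, 0.08, 0.260),
    (ACC_L, SMPFC_R, -0.09, 0.07, 0.250),
    (ACC_R, SMPFC_R, -0.10, 0.08, 0.275),
)

#: Episode shifts of the planted-edge summation score relative to the
#: overall patient mean (sum of planted patient means = -0.38), chosen so
#: the episode-level means of the score are depressive -0.55, manic 0.046,
#: remission -0.46.
DEFAULT_EPISODE_EFFECT = {"depressive": -0.17, "manic": 0.426, "remission": -0.08}
DEFAULT_EPISODE_COUNTS = {"depressive": 35, "manic": 19, "remission": 29}

#: Default structural-covariance targets: a coherent anterior-midline
#: module (all pairs among ACC L/R and sMPFC L/R at r = 0.5) with no group
#: difference, matching the null structural findings.  The within-hemisphere
#: sibling pairs must be planted along with the four cross pairs: a clique
#: with strong cross-correlations but background-level sibling correlations
#: is not a valid (positive semi-definite) correlation pattern.
DEFAULT_STRUCTURAL_EFFECT: tuple[tuple[int, int, float, float], ...] = (
    (31, 23, 0.5, 0.5), (32, 23, 0.5, 0.5), (31, 24, 0.5, 0.5),
    (32, 24, 0.5, 0.5), (32, 31, 0.5, 0.5), (24, 23, 0.5, 0.5),
)

GROUP_PATIENT = 1
GROUP_CONTROL = -1

_STREAM_VOLUMES = 3
_STREAM_TIMESERIES = 5
_STREAM_MOTION = 7
_STREAM_COVARIATES = 11
_STREAM_CLINICAL = 13
_STREAM_NUISANCE = 17


@dataclass
class CovariateModel:
    """Group demographic distributions and linear confounding slopes.

    Means/SDs default to the study-cohort demographics (patients slightly
    older, slightly less educated).  ``edge_slopes`` shift the planted-edge
    Fisher-z targets per unit covariate (centred at the pooled reference);
    ``volume_slopes`` shift every regional volume per unit covariate.
    """

    age_mean: dict = field(default_factory=lambda: {"A": 25.63, "B": 23.3})
    age_sd: dict = field(default_factory=lambda: {"A": 5.59, "B": 4.6})
    education_mean: dict = field(default_factory=lambda: {"A": 13.0, "B": 14.0})
    education_sd: dict = field(default_factory=lambda: {"A": 2.9, "B": 2.1})
    sex_male_prop: dict = field(default_factory=lambda: {"A": 37 / 83, "B": 47 / 94})
    edge_slopes: dict = field(
        default_factory=lambda: {"age": -0.004, "sex": 0.0, "education": 0.004}
    )
    volume_slopes: dict = field(
        default_factory=lambda: {"age": -0.01, "sex": 0.05, "education": 0.01}
    )
    reference: dict = field(
        default_factory=lambda: {"age": 24.4, "sex": 0.475, "education": 13.5}
    )


@dataclass
class MotionModel:
    """Random-walk head motion plus optional persistent spikes.

    ``fd_scale`` is the target mean framewise displacement (mm) per group;
    ``spike_prob`` is the per-transition probability of a step jump of
    ``spike_mm`` millimetres; ``intensity_spike_sd`` adds a global intensity
    offset (in signal SDs) to the spiked frames so intensity scrubbing has
    something to find.
    """

    fd_scale: dict = field(default_factory=lambda: {"A": 0.15, "B": 0.13})
    spike_prob: float = 0.0
    spike_mm: float = 1.0
    intensity_spike_sd: float = 0.0


@dataclass
class CohortConfig:
    n_group_A: int = 83
    n_group_B: int = 94
    n_regions: int = 90
    n_volumes: int = 250
    tr_seconds: float = 2.0
    planted_edges: tuple = DEFAULT_PLANTED_EDGES
    episode_counts: dict = field(default_factory=lambda: dict(DEFAULT_EPISODE_COUNTS))
    episode_effect: dict = field(default_factory=lambda: dict(DEFAULT_EPISODE_EFFECT))
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    motion_model: MotionModel = field(default_factory=MotionModel)
    #: group-level structural covariance targets (i, j, r_A, r_B), 1-based
    structural_effect: tuple = DEFAULT_STRUCTURAL_EFFECT
    couple_structural: bool = False
    background_r: float = 0.10
    background_structural_r: float = 0.10
    volume_mean: float = 5.0
    volume_sd: float = 1.0
    nuisance_leak: float = 0.1
    clinical_association: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if min(self.n_group_A, self.n_group_B, self.n_regions, self.n_volumes) <= 0:
            raise ValueError("counts must be positive")
        if self.episode_counts and sum(self.episode_counts.values()) != self.n_group_A:
            raise ValueError("episode counts must sum to n_group_A")
        for i, j, za, zb, sd in self.planted_edges:
            if i == j or not (1 <= i <= self.n_regions and 1 <= j <= self.n_regions):
                raise ValueError(f"planted edge ({i}, {j}) out of range")
            if not (np.isfinite(za) and np.isfinite(zb)):
                raise ValueError("planted edge means must be finite")
            if sd <= 0:
                raise ValueError("planted edge sd_z must be positive")
        for i, j, ra, rb in self.structural_effect:
            if i == j or not (1 <= i <= self.n_regions and 1 <= j <= self.n_regions):
                raise ValueError(f"structural edge ({i}, {j}) out of range")
            if max(abs(ra), abs(rb)) >= 1:
                raise ValueError(
                    f"infeasible structural correlation target ({ra}, {rb}): |r| >= 1"
                )
        if abs(self.background_r) >= 1 or abs(self.background_structural_r) >= 1:
            raise ValueError("infeasible background correlation: |r| >= 1")

    def resolved_structural_effect(self) -> tuple:
        """Structural targets, with the coupling flag planting a group
        difference matched to the planted functional pairs.

        Coupling decouples the planted cross pairs in patients (r 0.15 vs
        0.65 in controls) while keeping the remaining pairs among the
        planted regions at 0.55 in both groups, so the pattern stays a
        feasible correlation matrix.
        """
        if not self.couple_structural:
            return tuple(self.structural_effect)
        planted = {frozenset((i, j)) for (i, j, *_rest) in self.planted_edges}
        regions = sorted({r for pair in planted for r in pair})
        effect = [(i, j, 0.15, 0.65) for (i, j, *_rest) in self.planted_edges]
        for a_i in range(len(regions)):
            for b_i in range(a_i + 1, len(regions)):
                pair = frozenset((regions[a_i], regions[b_i]))
                if pair not in planted:
                    effect.append((regions[b_i], regions[a_i], 0.55, 0.55))
        return tuple(effect)

    def planted_positions(self, edge_index: EdgeIndex | None = None) -> np.ndarray:
        idx = edge_index or EdgeIndex(self.n_regions)
        return np.array(
            [idx.position(i - 1, j - 1) for (i, j, *_r) in self.planted_edges], dtype=int
        )


@dataclass
class SubjectRecord:
    subject_id: str
    group: int  # +1 patient, -1 control
    episode: str | None
    covariates: dict  # age (years), sex (1 = male), education (years), ...
    clinical_scores: dict  # HAMD / HAMA / YMRS, patients only
    roi_volumes: np.ndarray  # (n_regions,)
    roi_timeseries: np.ndarray  # (T, n_regions)
    motion_params: np.ndarray  # (T, 6): translations mm, rotations rad
    nuisance_signals: np.ndarray  # (T, 2): WM-like, CSF-like


def null_config(**overrides) -> CohortConfig:
    """A configuration with every group effect and confound switched off;
    useful for type-I-error calibration."""
    n_a = overrides.pop("n_group_A", 40)
    base = dict(
        n_group_A=n_a,
        n_group_B=overrides.pop("n_group_B", 40),
        planted_edges=(),
        structural_effect=(),
        episode_counts={"remission": n_a},
        episode_effect={"remission": 0.0},
        covariate_model=CovariateModel(
            age_mean={"A": 24.0, "B": 24.0},
            age_sd={"A": 5.0, "B": 5.0},
            education_mean={"A": 13.5, "B": 13.5},
            education_sd={"A": 2.5, "B": 2.5},
            sex_male_prop={"A": 0.5, "B": 0.5},
            edge_slopes={"age": 0.0, "sex": 0.0, "education": 0.0},
            volume_slopes={"age": 0.0, "sex": 0.0, "education": 0.0},
        ),
    )
    base.update(overrides)
    return CohortConfig(**base)


def _rng(config: CohortConfig, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, index])


def _ar1(rng: np.random.Generator, t: int, phi: float = 0.9) -> np.ndarray:
    e = rng.standard_normal(t)
    x = np.empty(t)
    x[0] = e[0]
    for i in range(1, t):
        x[i] = phi * x[i - 1] + np.sqrt(1 - phi**2) * e[i]
    return x


def _nearest_corr(c: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite correlation matrix."""
    w, v = np.linalg.eigh(c)
    if w.min() > floor:
        return c
    w = np.clip(w, floor, None)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.diag(c2))
    return c2 / np.outer(d, d)


def _spike_steps(rng: np.random.Generator, t: int, model: MotionModel):
    spikes = rng.random(t - 1) < model.spike_prob
    signs = rng.choice([-1.0, 1.0], size=t - 1)
    return spikes, signs


def simulate_motion(config: CohortConfig, subject_index: int) -> np.ndarray:
    """T x 6 motion-parameter matrix for one subject (deterministic in seed).

    Continuous random-walk drift scaled to the group's target mean FD, plus
    persistent step jumps at spike transitions so exactly the post-spike
    frame exceeds the FD threshold.
    """
    motion, _ = _simulate_motion_with_spikes(config, subject_index)
    return motion


def _simulate_motion_with_spikes(config: CohortConfig, subject_index: int):
    t = config.n_volumes
    if t < 2:
        raise ValueError("need at least two volumes")
    model = config.motion_model
    group = "A" if subject_index < config.n_group_A else "B"
    rng = _rng(config, _STREAM_MOTION, subject_index)

    # mean FD of a Gaussian random walk: 6 * sigma * sqrt(2/pi) * ... with
    # rotations scaled to contribute equally on a 50 mm sphere
    sigma_t = model.fd_scale[group] / (6.0 * np.sqrt(2.0 / np.pi))
    sigma_r = sigma_t / 50.0
    steps = np.empty((t - 1, 6))
    steps[:, :3] = rng.standard_normal((t - 1, 3)) * sigma_t
    steps[:, 3:] = rng.standard_normal((t - 1, 3)) * sigma_r

    spikes, signs = _spike_steps(rng, t, model)
    steps[spikes, 0] += signs[spikes] * model.spike_mm

    motion = np.zeros((t, 6))
    motion[1:] = np.cumsum(steps, axis=0)
    spike_frames = np.zeros(t, dtype=bool)
    spike_frames[1:] = spikes
    return motion, spike_frames


def _draw_covariates(config: CohortConfig, group: str, n: int, rng) -> dict:
    cm = config.covariate_model
    return {
        "age": rng.normal(cm.age_mean[group], cm.age_sd[group], n),
        "sex": (rng.random(n) < cm.sex_male_prop[group]).astype(float),
        "education": rng.normal(cm.education_mean[group], cm.education_sd[group], n),
    }


def _volume_covariance(config: CohortConfig, group: str) -> np.ndarray:
    r = config.n_regions
    c = np.full((r, r), config.background_structural_r)
    np.fill_diagonal(c, 1.0)
    effect = config.resolved_structural_effect()
    for i, j, ra, rb in effect:
        val = ra if group == "A" else rb
        c[i - 1, j - 1] = c[j - 1, i - 1] = val
    c2 = _nearest_corr(c)
    if effect:
        ii = np.array([e[0] - 1 for e in effect])
        jj = np.array([e[1] - 1 for e in effect])
        drift = np.abs(c2[ii, jj] - c[ii, jj]).max()
        if drift > 0.05:
            warnings.warn(
                f"planted structural pattern is not jointly feasible; "
                f"PSD projection moved a target by {drift:.3f}",
                stacklevel=3,
            )
    return c2


def _episode_labels(config: CohortConfig, rng) -> list[str]:
    labels: list[str] = []
    for name, count in config.episode_counts.items():
        labels.extend([name] * count)
    labels = list(np.array(labels)[rng.permutation(len(labels))])
    return labels


def _clinical_scores(episode: str, rng, assoc: float, planted_sum: float) -> dict:
    if episode == "depressive":
        hamd, ymrs = rng.uniform(17, 30), rng.uniform(0, 11)
    elif episode == "manic":
        hamd, ymrs = rng.uniform(0, 16), rng.uniform(12, 30)
    else:
        hamd, ymrs = rng.uniform(0, 16), rng.uniform(0, 11)
    hama = abs(rng.normal(9.3, 8.7))
    # zero true association with connectivity unless explicitly requested
    hamd = hamd + assoc * planted_sum
    return {"HAMD": float(hamd), "HAMA": float(hama), "YMRS": float(ymrs)}


def simulate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate the full synthetic cohort (deterministic given the seed)."""
    config.validate()
    idx = EdgeIndex(config.n_regions)
    t, r = config.n_volumes, config.n_regions
    n_a, n_b = config.n_group_A, config.n_group_B
    cm = config.covariate_model

    cov_rng = _rng(config, _STREAM_COVARIATES)
    cov_a = _draw_covariates(config, "A", n_a, cov_rng)
    cov_b = _draw_covariates(config, "B", n_b, cov_rng)
    episodes = _episode_labels(config, cov_rng) if config.episode_counts else [None] * n_a

    # group volumes: latent correlated profiles + covariate shifts
    vol_rng = _rng(config, _STREAM_VOLUMES)
    records: list[SubjectRecord] = []
    vols = {}
    for group, n in (("A", n_a), ("B", n_b)):
        chol = np.linalg.cholesky(_volume_covariance(config, group))
        z = vol_rng.standard_normal((n, r))
        vols[group] = config.volume_mean + config.volume_sd * (z @ chol.T)
    for group, covs in (("A", cov_a), ("B", cov_b)):
        for name, slope in cm.volume_slopes.items():
            vols[group] += np.outer(covs[name] - cm.reference[name], np.ones(r)) * slope

    # expected sample variance of the AR(1) nuisance over a T-frame window
    # (autocorrelation deflates it below 1); used to size the effective leak
    phi = 0.9
    rho = phi ** np.arange(1, t)
    ar1_var = 1.0 - (2.0 / (t - 1)) * np.sum((1.0 - np.arange(1, t) / t) * rho)

    # per-subject latent Fisher-z SD deflated for finite-T sampling noise
    latent_sd = np.array(
        [
            np.sqrt(max(sd**2 - 1.0 / (t - 3), 0.05**2))
            for (_i, _j, _za, _zb, sd) in config.planted_edges
        ]
    )
    n_planted = max(len(config.planted_edges), 1)

    clin_rng = _rng(config, _STREAM_CLINICAL)
    subject_index = 0
    for group, n, covs in (("A", n_a, cov_a), ("B", n_b, cov_b)):
        label = GROUP_PATIENT if group == "A" else GROUP_CONTROL
        for s in range(n):
            rng = _rng(config, _STREAM_TIMESERIES, subject_index)
            episode = episodes[s] if group == "A" else None

            # planted-edge targets on the Fisher-z scale
            z_targets = []
            for e, (i, j, za, zb, sd) in enumerate(config.planted_edges):
                z = (za if group == "A" else zb) + latent_sd[e] * rng.standard_normal()
                for name, slope in cm.edge_slopes.items():
                    z += slope * (covs[name][s] - cm.reference[name])
                if episode is not None and config.episode_effect:
                    z += config.episode_effect.get(episode, 0.0) / n_planted
                z_targets.append(z)

            c = np.full((r, r), float(config.background_r))
            np.fill_diagonal(c, 1.0)
            for (i, j, *_rest), z in zip(config.planted_edges, z_targets):
                c[i - 1, j - 1] = c[j - 1, i - 1] = np.tanh(z)

            nus_rng = _rng(config, _STREAM_NUISANCE, subject_index)
            nuisance = np.column_stack([_ar1(nus_rng, t), _ar1(nus_rng, t)])
            if config.nuisance_leak:
                # the leak adds correlated signal; choose the latent
                # correlation so the *total* series realizes the target:
                # C_latent = C_target * sqrt((1+|l_i|^2)(1+|l_j|^2)) - l_i.l_j
                # with this subject's effective leak weights
                leak = nus_rng.standard_normal((2, r)) * config.nuisance_leak
                lam = leak * np.sqrt(ar1_var)
                norms2 = (lam**2).sum(axis=0)
                scale = np.sqrt(np.outer(1.0 + norms2, 1.0 + norms2))
                c = c * scale - lam.T @ lam
                np.fill_diagonal(c, 1.0)
            c = _nearest_corr(c)
            chol = np.linalg.cholesky(c)
            ts = rng.standard_normal((t, r)) @ chol.T
            if config.nuisance_leak:
                ts = ts + nuisance @ leak

            motion, spike_frames = _simulate_motion_with_spikes(config, subject_index)
            if config.motion_model.intensity_spike_sd and spike_frames.any():
                ts[spike_frames] += config.motion_model.intensity_spike_sd

            planted_sum = float(np.sum(z_targets)) if z_targets else 0.0
            if group == "A":
                clinical = _clinical_scores(
                    episode or "remission", clin_rng, config.clinical_association, planted_sum
                )
                extra = {
                    "illness_duration": float(abs(clin_rng.normal(53.7, 57.1))),
                    "age_of_onset": float(clin_rng.normal(21.4, 5.3)),
                }
            else:
                clinical, extra = {}, {}

            records.append(
                SubjectRecord(
                    subject_id=f"sub-{subject_index + 1:04d}",
                    group=label,
                    episode=episode,
                    covariates={
                        "age": float(covs["age"][s]),
                        "sex": float(covs["sex"][s]),
                        "education": float(covs["education"][s]),
                        **extra,
                    },
                    clinical_scores=clinical,
                    roi_volumes=vols[group][s],
                    roi_timeseries=ts,
                    motion_params=motion,
                    nuisance_signals=nuisance,
                )
            )
            subject_index += 1
    return records


# ---------------------------------------------------------------------------
# plain-text cohort I/O


def cohort_arrays(subjects: list[SubjectRecord]):
    """Stack per-subject fields into analysis arrays.

    Returns (labels, volumes, covariate matrix [age, sex, education]) in
    subject order.
    """
    labels = np.array([s.group for s in subjects])
    volumes = np.vstack([s.roi_volumes for s in subjects])
    covs = np.column_stack(
        [
            [s.covariates["age"] for s in subjects],
            [s.covariates["sex"] for s in subjects],
            [s.covariates["education"] for s in subjects],
        ]
    )
    return labels, volumes, covs


def write_cohort(subjects: list[SubjectRecord], outdir) -> str:
    """Write metadata and per-subject TSVs plus a manifest; returns the
    manifest path."""
    import os

    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    meta_rows, manifest_rows = [], []
    for s in subjects:
        base = os.path.join(outdir, s.subject_id)
        paths = {
            "volumes": base + "_volumes.tsv",
            "timeseries": base + "_timeseries.tsv",
            "motion": base + "_motion.tsv",
            "nuisance": base + "_nuisance.tsv",
        }
        np.savetxt(paths["volumes"], s.roi_volumes[None, :], delimiter="\t")
        np.savetxt(paths["timeseries"], s.roi_timeseries, delimiter="\t")
        np.savetxt(paths["motion"], s.motion_params, delimiter="\t")
        np.savetxt(paths["nuisance"], s.nuisance_signals, delimiter="\t")
        meta_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "episode": s.episode or "",
                **s.covariates,
                **s.clinical_scores,
            }
        )
        manifest_rows.append({"subject_id": s.subject_id, **paths})
    meta_path = os.path.join(outdir, "participants.tsv")
    manifest_path = os.path.join(outdir, "manifest.tsv")
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_cohort(manifest_path) -> list[SubjectRecord]:
    """Re-load a cohort written by :func:`write_cohort`."""
    import os

    import pandas as pd

    mdir = os.path.dirname(os.path.abspath(manifest_path))
    manifest = pd.read_csv(manifest_path, sep="\t")
    meta = pd.read_csv(os.path.join(mdir, "participants.tsv"), sep="\t").set_index(
        "subject_id"
    )
    subjects = []
    known = {"group", "episode", "age", "sex", "education", "illness_duration",
             "age_of_onset"}
    for _, row in manifest.iterrows():
        m = meta.loc[row["subject_id"]]
        covariates = {
            k: float(m[k])
            for k in ("age", "sex", "education", "illness_duration", "age_of_onset")
            if k in m and pd.notna(m[k])
        }
        clinical = {
            k: float(m[k]) for k in meta.columns if k not in known and pd.notna(m[k])
        }
        subjects.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                group=int(m["group"]),
                episode=(m["episode"] if isinstance(m["episode"], str) and m["episode"] else None),
                covariates=covariates,
                clinical_scores=clinical,
                roi_volumes=np.loadtxt(row["volumes"], delimiter="\t"),
                roi_timeseries=np.loadtxt(row["timeseries"], delimiter="\t"),
                motion_params=np.loadtxt(row["motion"], delimiter="\t"),
                nuisance_signals=np.loadtxt(row["nuisance"], delimiter="\t"),
            )
        )
    return subjects
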