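"""Synthetic typing sessions and cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised — and its parameter recovery
checked — without any data download:

* hold times and interkey gaps are log-normal with per-subject log-scale
  parameters; for iid log-normal intervals the log-ratio fluctuation
  statistic converges to ``sqrt(2) * sigma_log``, giving an analytic map
  from the published group-level statistics to generator parameters;
* a small fraction of interkey gaps are replaced by negative overlaps
  (rollover typing: the next key goes down before the previous comes up);
* rare glitch outliers inflate intervals by a factor of 30-100, at the
  sub-percent rates seen in the archival recordings;
* clinical covariates (UPDRS-III, sTap, afTap, nQi) are drawn from
  truncated group normals, and disease severity is linked to typing speed
  and session length through a shared latent with a configurable target
  rank correlation.

Everything is fully deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import GROUPS, SubjectMetadata, TypingSession, KeystrokeEvent

__all__ = [
    "TypistProfile",
    "GroupSpec",
    "CohortSpec",
    "SessionTruth",
    "CohortData",
    "generate_session",
    "generate_cohort",
    "write_cohort",
    "default_cohort_spec",
]

_LETTERS = np.array(list("abcdefghijklmnopqrstuvwxyz"))

#: Spearman target -> Pearson correlation of the underlying bivariate normal
def _pearson_for_spearman(rho_s: float) -> float:
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass(frozen=True)
class TypistProfile:
    """Latent parameters of one subject's typing behaviour.

    ``mu_logIL`` may be left ``None`` together with a
    ``words_per_min_target``, in which case the interkey location parameter
    is solved so the session's expected pace matches the target:
    mean press-to-press interval = space_rate * 60 / wpm, of which
    ``exp(mu_logHL + sigma_logHL^2/2)`` is spent holding keys.
    """

    mu_logHL: float = math.log(0.055)
    sigma_logHL: float = 0.35
    mu_logIL: float | None = None
    sigma_logIL: float = 0.81
    rollover_prob: float = 0.005
    outlier_rate: float = 0.005
    space_rate: float = 1.0 / 6.0
    backspace_rate: float = 0.03  # typists correct freely; excluded by the restricted filter
    n_keystrokes: int = 1500
    words_per_min_target: float | None = 100.0

    MIN_MEAN_GAP = 0.004  # seconds; floor when solving for mu_logIL

    def __post_init__(self) -> None:
        if self.sigma_logHL <= 0 or self.sigma_logIL <= 0:
            raise ValueError("sigmas must be positive")
        for name in ("rollover_prob", "outlier_rate", "space_rate", "backspace_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_keystrokes < 10:
            raise ValueError("n_keystrokes must be >= 10")
        if self.mu_logIL is None and self.words_per_min_target is None:
            raise ValueError("provide mu_logIL or words_per_min_target")

    @property
    def mean_hold(self) -> float:
        return math.exp(self.mu_logHL + self.sigma_logHL**2 / 2.0)

    def resolved_mu_logIL(self) -> float:
        if self.mu_logIL is not None:
            return self.mu_logIL
        target_pl = self.space_rate * 60.0 / self.words_per_min_target
        mean_gap = max(target_pl - self.mean_hold, self.MIN_MEAN_GAP)
        return math.log(mean_gap) - self.sigma_logIL**2 / 2.0


@dataclass(frozen=True)
class SessionTruth:
    """Ground-truth labels of the stochastic choices inside one session."""

    profile: TypistProfile
    rollover_gap_idx: np.ndarray   # indices into the IL series
    outlier_hold_idx: np.ndarray   # indices into the HL series
    outlier_gap_idx: np.ndarray    # indices into the IL series


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_session(
    profile: TypistProfile,
    seed,
    subject_id: str = "synthetic",
    visit_index: int = 1,
    return_truth: bool = False,
):
    """Simulate one typing session.

    Hold times and interkey gaps are log-normal; with probability
    ``rollover_prob`` a gap is replaced by a negative overlap (10-90% of
    the preceding hold, so press order is preserved); with probability
    ``outlier_rate`` a hold or positive gap is inflated by a uniform
    factor in [30, 100].  Keys are "space" with ``space_rate``, else
    uniform letters.  Deterministic given the seed.
    """
    rng = _rng(seed)
    n = profile.n_keystrokes
    mu_il = profile.resolved_mu_logIL()

    holds = rng.lognormal(profile.mu_logHL, profile.sigma_logHL, n)
    gaps = rng.lognormal(mu_il, profile.sigma_logIL, n - 1)

    roll = rng.random(n - 1) < profile.rollover_prob
    overlap_frac = rng.uniform(0.1, 0.9, int(roll.sum()))
    gaps[roll] = -overlap_frac * holds[:-1][roll]

    out_h = rng.random(n) < profile.outlier_rate
    holds[out_h] *= rng.uniform(30.0, 100.0, int(out_h.sum()))
    out_g = (rng.random(n - 1) < profile.outlier_rate) & (gaps > 0)
    gaps[out_g] *= rng.uniform(30.0, 100.0, int(out_g.sum()))

    press = np.concatenate([[0.0], np.cumsum(holds[:-1] + gaps)])
    release = press + holds
    u = rng.random(n)
    letters = _LETTERS[rng.integers(0, len(_LETTERS), n)]
    keys = np.where(
        u < profile.space_rate,
        "space",
        np.where(u < profile.space_rate + profile.backspace_rate, "backspace", letters),
    )

    events = [
        KeystrokeEvent(str(k), float(p), float(r))
        for k, p, r in zip(keys, press, release)
    ]
    session = TypingSession(
        subject_id=subject_id, visit_index=visit_index, events=events, source="synthetic"
    )
    if not return_truth:
        return session
    truth = SessionTruth(
        profile=profile,
        rollover_gap_idx=np.flatnonzero(roll),
        outlier_hold_idx=np.flatnonzero(out_h),
        outlier_gap_idx=np.flatnonzero(out_g),
    )
    return session, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Generator calibration for one cohort group.

    Fluctuation targets are stated on the observable scale (the group mean
    and between-subject SD of the log-ratio statistic); the corresponding
    log-normal sigma is target / sqrt(2).  Tapping scores are msec; session
    length and typing speed are drawn from truncated normals; the
    ``*_updrs_link`` fields are target Spearman correlations between
    UPDRS-III and typing speed / session length within the group.
    """

    name: str
    n_subjects: int
    il_sd_target: float
    il_sd_spread: float
    hl_sd_target: float
    hl_sd_spread: float
    mean_hold_s: float = 0.055
    rollover_prob: float = 0.005
    outlier_rate: float = 0.005
    space_rate: float = 1.0 / 6.0
    backspace_rate: float = 0.03
    n_keystrokes_mean: float = 1500.0
    n_keystrokes_sd: float = 600.0
    n_keystrokes_min: int = 200
    speed_mean: float = 100.0
    speed_sd: float = 45.0
    speed_min: float = 20.0
    updrs_mean: float = 0.0
    updrs_sd: float = 1.0
    updrs_min: float = 0.0
    updrs_max: float = 60.0
    stap_mean: float = 170.0
    stap_sd: float = 20.0
    aftap_mean: float = 120.0
    aftap_sd: float = 25.0
    nqi_mean: float = 0.06
    nqi_sd: float = 0.06
    aftap_missing_n: int = 0
    speed_updrs_link: float = 0.0
    words_updrs_link: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in GROUPS:
            raise ValueError(f"group name must be one of {GROUPS}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort recipe: one GroupSpec per group plus the master seed."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        groups = tuple(GroupSpec(**g) for g in data["groups"])
        return cls(groups=groups, seed=int(data.get("seed", 0)))

    def to_yaml(self, path: str | Path) -> None:
        data = {"seed": self.seed, "groups": [asdict(g) for g in self.groups]}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def with_seed(self, seed: int) -> "CohortSpec":
        return CohortSpec(groups=self.groups, seed=seed)


@dataclass
class CohortData:
    sessions: list[TypingSession]
    metadata: list[SubjectMetadata]
    truth: pd.DataFrame  # one row per subject: every latent parameter


def _trunc_normal(rng, mean, sd, low=None, high=None, z=None):
    z = rng.standard_normal() if z is None else z
    v = mean + sd * z
    if low is not None:
        v = max(v, low)
    if high is not None:
        v = min(v, high)
    return v


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortData:
    """Generate sessions, metadata and a ground-truth table for a cohort.

    Per subject the severity latent z drives UPDRS-III directly, and typing
    speed / session length through the configured rank-correlation targets
    (Spearman targets are mapped to the Pearson correlation of the
    underlying bivariate normal).  The generation is fully determined by
    ``seed`` (default: the spec's own seed).
    """
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    sessions: list[TypingSession] = []
    metadata: list[SubjectMetadata] = []
    truth_rows = []
    group_seqs = master.spawn(len(spec.groups))
    for g, gseq in zip(spec.groups, group_seqs):
        grng = np.random.default_rng(gseq)
        missing_aftap = set(
            grng.choice(g.n_subjects, size=min(g.aftap_missing_n, g.n_subjects),
                        replace=False).tolist()
        )
        rho_speed = _pearson_for_spearman(g.speed_updrs_link)
        rho_words = _pearson_for_spearman(g.words_updrs_link)
        subj_seqs = gseq.spawn(g.n_subjects)
        for i, sseq in enumerate(subj_seqs):
            rng = np.random.default_rng(sseq)
            sid = f"{g.name}_{i + 1:03d}"

            z_sev = rng.standard_normal()
            updrs = _trunc_normal(rng, g.updrs_mean, g.updrs_sd,
                                  g.updrs_min, g.updrs_max, z=z_sev)
            z_speed = rho_speed * z_sev + math.sqrt(1 - rho_speed**2) * rng.standard_normal()
            speed = _trunc_normal(rng, g.speed_mean, g.speed_sd, g.speed_min, None, z=z_speed)
            z_words = rho_words * z_sev + math.sqrt(1 - rho_words**2) * rng.standard_normal()
            n_keys = int(round(_trunc_normal(rng, g.n_keystrokes_mean, g.n_keystrokes_sd,
                                             g.n_keystrokes_min, None, z=z_words)))

            sigma_il = max(0.05, rng.normal(g.il_sd_target, g.il_sd_spread) / math.sqrt(2))
            sigma_hl = max(0.05, rng.normal(g.hl_sd_target, g.hl_sd_spread) / math.sqrt(2))
            profile = TypistProfile(
                mu_logHL=math.log(g.mean_hold_s) - sigma_hl**2 / 2.0,
                sigma_logHL=sigma_hl,
                sigma_logIL=sigma_il,
                rollover_prob=g.rollover_prob,
                outlier_rate=g.outlier_rate,
                space_rate=g.space_rate,
                backspace_rate=g.backspace_rate,
                n_keystrokes=n_keys,
                words_per_min_target=speed,
            )
            session = generate_session(profile, rng, subject_id=sid)
            sessions.append(session)

            stap = max(1.0, rng.normal(g.stap_mean, g.stap_sd))
            aftap = max(1.0, rng.normal(g.aftap_mean, g.aftap_sd))
            nqi = max(0.0, rng.normal(g.nqi_mean, g.nqi_sd))
            metadata.append(
                SubjectMetadata(
                    subject_id=sid,
                    group=g.name,
                    updrs3=float(updrs),
                    stap=float(stap),
                    aftap=math.nan if i in missing_aftap else float(aftap),
                    nqi=float(nqi),
                )
            )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "group": g.name,
                    "z_severity": z_sev,
                    "updrs3": updrs,
                    "speed_target": speed,
                    "n_keystrokes": n_keys,
                    "sigma_logHL": sigma_hl,
                    "sigma_logIL": sigma_il,
                    "expected_hl_sd": math.sqrt(2) * sigma_hl,
                    "expected_il_sd": math.sqrt(2) * sigma_il,
                    "rollover_prob": g.rollover_prob,
                    "outlier_rate": g.outlier_rate,
                }
            )
    return CohortData(sessions=sessions, metadata=metadata, truth=pd.DataFrame(truth_rows))


def write_cohort(cohort: CohortData, outdir: str | Path) -> dict[str, Path]:
    """Emit canonical keystroke CSV, metadata CSV and the ground-truth CSV."""
    from .io import write_metadata, write_sessions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "keystrokes": outdir / "keystrokes.csv",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "ground_truth.csv",
    }
    write_sessions(cohort.sessions, paths["keystrokes"])
    write_metadata(cohort.metadata, paths["metadata"])
    cohort.truth.to_csv(paths["truth"], index=False)
    return paths


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The shipped reference calibration (``data/reference_cohort.yaml``)."""
    from importlib.resources import files

    path = files("pdkeys.data").joinpath("reference_cohort.yaml")
    with path.open() as fh:
        data = yaml.safe_load(fh)
    groups = tuple(GroupSpec(**g) for g in data["groups"])
    return CohortSpec(groups=groups, seed=seed)
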