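"""Synthetic five-group resting-state cohort generator.

Emulates the study design the pipeline targets: five diagnostic groups
(HS, aMCI, CDR0.5, CDR1, CDR2) of unequal size (31/50/25/36/10 by
default), one region x time signal matrix per subject (90 regions, 120
time points at a 3 s sampling interval), and a table of clinical scores
per subject.

Signal model — stationary multivariate Gaussian with a modular,
stage-dependent two-level factor structure.  Each region i belongs to a
module m(i) (modules follow the shipped lobe map), and

    x_i(t) = sqrt(w) * [ sqrt(1-c) * u_m(i)(t) + sqrt(c) * g(t) ] +
             sqrt(1-w) * e_i(t)

where ``u_m`` are independent module factors, ``g`` is a global factor
shared by every region, ``e_i`` is region-private signal, and independent
measurement noise of standard deviation ``noise_sd`` is added on top.
The implied correlation is ``w`` within a module and ``c * w`` between
modules (both shrunk by 1/(1+noise_sd^2) after noise): ``w``
(``module_corr``) sets a fixed modular baseline, and the group coupling
``c`` sets how coherent the modules are with one another.  The matrix is
positive definite for any w < 1 and c in [0, 1) by construction.

The stage parameter deliberately scales *between-module integration*, not
the within-module coupling.  At a fixed edge budget, raising within-module
dependence only concentrates edges inside modules and makes the
thresholded network more segregated — group-level global efficiency then
*falls* with coupling, the opposite of the stage ordering this cohort
must exhibit (integration high in aMCI and CDR1).  Raising between-module
coherence instead lets inter-lobe edges compete into the fixed budget and
integrates the graph, so global efficiency increases with the coupling.
See the methods note for the numerical evidence behind this choice.

Clinical scores are baseline + clinical_effect * score_SD * (subject's
realized mean off-diagonal correlation) + noise, so cognitive scores are
genuinely correlated with the network properties derived from the same
subject's series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import default_lobe_map
from .connectivity import TimeSeriesMatrix, write_timeseries_tsv

__all__ = [
    "GROUPS",
    "CLINICAL_SCORE_BASELINES",
    "CohortSpec",
    "SubjectRecord",
    "generate_subject",
    "generate_cohort",
    "cohort_table",
    "write_cohort",
    "load_cohort",
    "implied_covariance",
]

GROUPS = ("HS", "aMCI", "CDR0.5", "CDR1", "CDR2")

# (baseline, SD) per clinical score for a healthy cohort: global cognition
# (MMSE), span, naming, figure copy/recall, verbal memory, fluency,
# inhibition.  Healthy-subject anchors only; group means emerge through
# clinical_effect and are not prescribed per group.
CLINICAL_SCORE_BASELINES: dict[str, tuple[float, float]] = {
    "MMSE": (28.6, 1.9),
    "digit_span_backward": (4.3, 1.5),
    "K_BNT": (48.5, 7.5),
    "RCFT_copy": (32.2, 5.0),
    "SVLT_delayed": (7.4, 2.0),
    "RCFT_delayed": (15.0, 3.9),
    "stroop_color_reading": (87.7, 23.3),
    "COWAT_semantic": (32.4, 7.5),
    "COWAT_phonemic": (28.1, 10.8),
}


def _default_group_sizes() -> dict[str, int]:
    return {"HS": 31, "aMCI": 50, "CDR0.5": 25, "CDR1": 36, "CDR2": 10}


def _default_couplings() -> dict[str, float]:
    # Non-monotonic stage ordering: HS < aMCI > CDR0.5 < CDR1 > CDR2,
    # the integration pattern the pipeline is meant to resolve.
    return {"HS": 0.35, "aMCI": 0.75, "CDR0.5": 0.20, "CDR1": 0.65, "CDR2": 0.30}


@dataclass
class CohortSpec:
    """Generator configuration; the defaults are the shipped study conditions.

    ``coupling_by_group`` is the stage-dependent between-module coherence
    c in [0, 1); ``module_corr`` the within-module baseline correlation w.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    n_regions: int = 90
    n_timepoints: int = 120
    coupling_by_group: dict[str, float] = field(default_factory=_default_couplings)
    n_modules: int = 5
    noise_sd: float = 0.2
    clinical_effect: float = -8.0      # score SDs per unit realized coupling
    seed: int = 0
    module_corr: float = 0.45          # within-module baseline correlation w
    coupling_jitter_sd: float = 0.02   # subject-level spread of c
    clinical_noise_scale: float = 0.5  # score noise in units of score SD
    ar_coeff: float = 0.0              # optional AR(1) temporal filter

    def __post_init__(self) -> None:
        if self.n_regions <= 0 or self.n_timepoints <= 0 or self.n_modules <= 0:
            raise ValueError("counts must be positive")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not 0 <= self.module_corr < 1:
            raise ValueError("module_corr must be in [0, 1)")
        if not -1 < self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for group, c in self.coupling_by_group.items():
            if not 0 <= c < 1:
                raise ValueError(
                    f"coupling {c} for group {group!r} lies outside [0, 1): "
                    f"the implied covariance would not be positive definite")

    # -- region -> module layout -----------------------------------------

    def region_ids(self) -> list[str]:
        if self.n_regions == 90:
            return default_lobe_map()["region"].tolist()
        return [f"R{i:03d}" for i in range(self.n_regions)]

    def module_assignment(self) -> np.ndarray:
        """Module index per region; for the 90-region default, the lobes."""
        if self.n_regions == 90 and self.n_modules == 5:
            lm = default_lobe_map()
            lobes = sorted(lm["lobe"].unique())
            return lm["lobe"].map({l: i for i, l in enumerate(lobes)}).to_numpy()
        # generic fallback: contiguous blocks as equal as possible
        return (np.arange(self.n_regions) * self.n_modules) // self.n_regions


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    clinical_scores: dict[str, float]
    realized_coupling: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def implied_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Model covariance of the observed series (signal + measurement noise)."""
    c = spec.coupling_by_group[group]
    modules = spec.module_assignment()
    same = modules[:, None] == modules[None, :]
    w = spec.module_corr
    cov = np.where(same, w, c * w)
    np.fill_diagonal(cov, 1.0)
    return cov + spec.noise_sd**2 * np.eye(spec.n_regions)


def _ar1_filter(x: np.ndarray, phi: float) -> np.ndarray:
    """Stationary AR(1) over time, preserving the contemporaneous covariance."""
    if phi == 0:
        return x
    out = np.empty_like(x)
    out[:, 0] = x[:, 0]
    scale = np.sqrt(1 - phi**2)
    for t in range(1, x.shape[1]):
        out[:, t] = phi * out[:, t - 1] + scale * x[:, t]
    return out


def generate_subject(spec: CohortSpec, group: str, subject_seed: int,
                     subject_id: str | None = None):
    """Draw one subject: (TimeSeriesMatrix, SubjectRecord).

    Bitwise reproducible from (spec.seed, subject_seed).
    """
    if group not in spec.group_sizes:
        raise KeyError(f"group {group!r} not in spec.group_sizes")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))
    R, T = spec.n_regions, spec.n_timepoints
    modules = spec.module_assignment()
    w = spec.module_corr

    c = spec.coupling_by_group[group]
    if spec.coupling_jitter_sd > 0:
        c = float(np.clip(rng.normal(c, spec.coupling_jitter_sd), 0.0, 0.999))

    u = rng.standard_normal((spec.n_modules, T))  # module factors
    g = rng.standard_normal(T)                    # global integration factor
    e = rng.standard_normal((R, T))               # region-private signal
    x = (np.sqrt(w) * (np.sqrt(1 - c) * u[modules] + np.sqrt(c) * g)
         + np.sqrt(1 - w) * e)
    x = _ar1_filter(x, spec.ar_coeff)
    x = x + spec.noise_sd * rng.standard_normal((R, T))
    ts = TimeSeriesMatrix(x, spec.region_ids())

    corr = np.corrcoef(x)
    realized = float(corr[np.triu_indices(R, k=1)].mean())
    scores = {}
    for name, (base, sd) in CLINICAL_SCORE_BASELINES.items():
        scores[name] = float(
            base
            + spec.clinical_effect * sd * realized
            + spec.clinical_noise_scale * sd * rng.standard_normal()
        )
    sid = subject_id or f"sub-{subject_seed:04d}"
    return ts, SubjectRecord(sid, group, scores, realized_coupling=realized)


def generate_cohort(spec: CohortSpec):
    """All subjects of the cohort, deterministic given ``spec.seed``.

    Returns a list of (TimeSeriesMatrix, SubjectRecord), groups in
    canonical order, subjects numbered consecutively.
    """
    for group in spec.group_sizes:
        if group not in GROUPS:
            raise ValueError(f"unknown group label {group!r}")
    out = []
    idx = 0
    for group in GROUPS:
        if group not in spec.group_sizes:
            continue
        for _ in range(spec.group_sizes[group]):
            out.append(generate_subject(spec, group, idx, f"sub-{idx:04d}"))
            idx += 1
    return out


def cohort_table(subjects) -> pd.DataFrame:
    """Subject table: subject_id, group, one column per clinical score."""
    rows = []
    for _, rec in subjects:
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     **rec.clinical_scores})
    return pd.DataFrame(rows)


def write_cohort(subjects, out_dir) -> None:
    """Write per-subject time-series TSVs and the cohort table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts, rec in subjects:
        write_timeseries_tsv(ts, out / f"{rec.subject_id}.tsv")
    cohort_table(subjects).to_csv(out / "cohort.tsv", sep="\t", index=False,
                                  float_format="%.6g")


def load_cohort(cohort_dir):
    """Read back a cohort written by :func:`write_cohort`."""
    from .connectivity import read_timeseries_tsv

    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "cohort.tsv", sep="\t")
    subjects = []
    score_cols = [c for c in table.columns if c not in ("subject_id", "group")]
    for _, row in table.iterrows():
        ts = read_timeseries_tsv(cohort_dir / f"{row.subject_id}.tsv")
        rec = SubjectRecord(row.subject_id, row.group,
                            {c: float(row[c]) for c in score_cols})
        subjects.append((ts, rec))
    return subjects
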