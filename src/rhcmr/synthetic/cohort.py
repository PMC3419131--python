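"""Synthetic suspected-PH cohorts with the study's statistical structure.

Each group (no-PH / PH) is described by a marginal mean ± SD per metric, a
target Pearson correlation of each metric with catheter mPAP, optional
physiologic truncation bounds, a late-gadolinium-enhancement rate and
sub-study membership counts. Records are drawn from a one-factor Gaussian
copula: a latent standard normal drives mPAP, and each metric's latent is
correlated with it; marginals are truncated normals whose *parent* location
and scale are solved numerically so the truncated mean/SD equal the
specified values, and the latent correlation is calibrated by Gauss–Hermite
quadrature (NORTA) so the achieved Pearson correlation matches the target
despite the nonlinear marginal transforms.

Group membership is derived from the drawn mPAP against the 25 mmHg
threshold — the no-PH marginal is truncated above 25 and the PH marginal
below at 25, so the group/mPAP invariant holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy import optimize, stats as sps

from ..errors import NotPositiveDefiniteError, ValidationError
from ..stats import Group, PatientRecord, Subgroup

_UNBOUNDED_Z = 8.0  # bounds beyond this many target SDs are treated as absent


@dataclass(frozen=True)
class MetricSpec:
    """Marginal moments, mPAP correlation and truncation bounds for one metric."""

    mean: float
    sd: float
    corr_mpap: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError(f"metric sd must be > 0, got {self.sd}")
        if not -1.0 < self.corr_mpap < 1.0:
            raise ValidationError(f"corr_mpap must be in (-1, 1), got {self.corr_mpap}")


@dataclass
class GroupSpec:
    """One group's size, mPAP marginal, metric marginals and LGE rate."""

    n: int
    mpap: MetricSpec  # corr_mpap ignored (it is the anchor variable)
    metrics: dict[str, MetricSpec]
    lge_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lge_rate <= 1.0:
            raise ValidationError("lge_rate must be in [0, 1]")


@dataclass
class CohortSpec:
    """Full recipe: groups, subgroup mix, sub-study sizes, extra exclusions."""

    groups: dict[Group, GroupSpec]
    subgroup_counts: dict[Subgroup, int] = field(default_factory=dict)
    subsets: dict[str, dict[Group, int]] = field(default_factory=dict)
    n_non_diagnostic: int = 0


def _spec_from_mapping(d: Mapping) -> CohortSpec:
    def metric(m: Mapping) -> MetricSpec:
        return MetricSpec(
            mean=float(m["mean"]),
            sd=float(m["sd"]),
            corr_mpap=float(m.get("corr_mpap", 0.0)),
            lower=float(m.get("lower", -math.inf)),
            upper=float(m.get("upper", math.inf)),
        )

    groups: dict[Group, GroupSpec] = {}
    for gname, g in d["groups"].items():
        groups[Group(gname)] = GroupSpec(
            n=int(g["n"]),
            mpap=metric(g["mpap"]),
            metrics={k: metric(v) for k, v in g.get("metrics", {}).items()},
            lge_rate=float(g.get("lge_rate", 0.0)),
        )
    return CohortSpec(
        groups=groups,
        subgroup_counts={Subgroup(k): int(v) for k, v in d.get("subgroup_counts", {}).items()},
        subsets={
            name: {Group(g): int(n) for g, n in sub.items()}
            for name, sub in d.get("subsets", {}).items()
        },
        n_non_diagnostic=int(d.get("n_non_diagnostic", 0)),
    )


def load_cohort_spec(path) -> CohortSpec:
    """Read a cohort spec from a YAML file."""
    with open(path) as fh:
        return _spec_from_mapping(yaml.safe_load(fh))


def default_cohort_spec() -> CohortSpec:
    """The packaged default: a 39 no-PH / 194 PH referral cohort."""
    text = resources.files("rhcmr.data").joinpath("cohort_default.yaml").read_text()
    return _spec_from_mapping(yaml.safe_load(text))


# ---------------------------------------------------------------- marginals


@dataclass(frozen=True)
class _Marginal:
    """A truncated normal in parent parameterization, ready to transform z."""

    mu: float
    sigma: float
    lower: float
    upper: float

    @property
    def a(self) -> float:
        return (self.lower - self.mu) / self.sigma

    @property
    def b(self) -> float:
        return (self.upper - self.mu) / self.sigma

    def ppf_of_z(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal latents through the copula: F⁻¹(Φ(z))."""
        if math.isinf(self.a) and math.isinf(self.b):
            return self.mu + self.sigma * z
        # clip away u = 0/1 at extreme latents (quadrature tail nodes), where
        # ppf would return the infinite bound of a one-sided truncation
        u = np.clip(sps.norm.cdf(z), 1e-15, 1.0 - 1e-15)
        return sps.truncnorm.ppf(u, self.a, self.b, loc=self.mu, scale=self.sigma)

    def moments(self) -> tuple[float, float]:
        if math.isinf(self.a) and math.isinf(self.b):
            return self.mu, self.sigma
        m, v = sps.truncnorm.stats(self.a, self.b, loc=self.mu, scale=self.sigma, moments="mv")
        return float(m), float(math.sqrt(v))


def match_truncated_normal(spec: MetricSpec) -> _Marginal:
    """Parent (μ, σ) whose truncation to [lower, upper] has the target mean/SD.

    Bounds further than 8 target SDs from the mean are dropped (the
    truncation is numerically inert). Raises ``ValidationError`` when no
    truncated normal can reach the requested moments (e.g. a lower-truncated
    normal cannot have (mean − lower)/SD ≤ 1).
    """
    lower, upper = spec.lower, spec.upper
    if not math.isinf(lower) and (spec.mean - lower) / spec.sd > _UNBOUNDED_Z:
        lower = -math.inf
    if not math.isinf(upper) and (upper - spec.mean) / spec.sd > _UNBOUNDED_Z:
        upper = math.inf
    if math.isinf(lower) and math.isinf(upper):
        return _Marginal(spec.mean, spec.sd, lower, upper)
    if not math.isinf(lower) and math.isinf(upper) and (spec.mean - lower) / spec.sd <= 1.0:
        raise ValidationError(
            f"truncated normal on [{lower}, inf) cannot reach mean {spec.mean}, sd {spec.sd}: "
            "(mean - lower)/sd must exceed 1"
        )
    if not math.isinf(upper) and math.isinf(lower) and (upper - spec.mean) / spec.sd <= 1.0:
        raise ValidationError(
            f"truncated normal on (-inf, {upper}] cannot reach mean {spec.mean}, sd {spec.sd}"
        )

    def residual(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        m, s = _Marginal(mu, math.exp(log_sigma), lower, upper).moments()
        return np.array([m - spec.mean, s - spec.sd])

    for mu0, s0 in ((spec.mean, spec.sd), (spec.mean - spec.sd, 1.5 * spec.sd),
                    (spec.mean + spec.sd, 1.5 * spec.sd), (spec.mean - 2 * spec.sd, 2.5 * spec.sd)):
        sol = optimize.root(residual, x0=[mu0, math.log(s0)], method="hybr")
        if sol.success and np.max(np.abs(sol.fun)) < 1e-8 * spec.sd:
            return _Marginal(float(sol.x[0]), float(math.exp(sol.x[1])), lower, upper)
    raise ValidationError(
        f"could not moment-match truncated normal (mean {spec.mean}, sd {spec.sd}, "
        f"bounds [{lower}, {upper}])"
    )


# ----------------------------------------------------------- copula (NORTA)

_GH_NODES = 48


def _achieved_pearson(m1: _Marginal, m2: _Marginal, rho_latent: float) -> float:
    """Pearson corr of (F₁⁻¹(Φ(z₁)), F₂⁻¹(Φ(z₂))) at latent corr ρ, by quadrature."""
    x, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    w = w / w.sum()
    z1 = x[:, None]
    z2 = rho_latent * z1 + math.sqrt(max(0.0, 1 - rho_latent**2)) * x[None, :]
    g1 = m1.ppf_of_z(np.broadcast_to(z1, z2.shape))
    g2 = m2.ppf_of_z(z2)
    ww = w[:, None] * w[None, :]
    mean1, sd1 = m1.moments()
    mean2, sd2 = m2.moments()
    cov = float((ww * (g1 - mean1) * (g2 - mean2)).sum())
    return cov / (sd1 * sd2)


def calibrate_latent_corr(m1: _Marginal, m2: _Marginal, target: float) -> float:
    """Latent normal correlation whose transformed Pearson corr hits ``target``."""
    if target == 0.0:
        return 0.0
    untruncated = all(math.isinf(v) for v in (m1.a, m1.b, m2.a, m2.b))
    if untruncated:
        return target

    def f(rho: float) -> float:
        return _achieved_pearson(m1, m2, rho) - target

    hi = 0.999
    lo = -0.999
    f_hi, f_lo = f(hi), f(lo)
    if (target > 0 and f_hi < 0) or (target < 0 and f_lo > 0):
        raise NotPositiveDefiniteError(
            f"target correlation {target} is unattainable under the marginal truncations"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


# ------------------------------------------------------------------ sampler


def _largest_remainder(counts: dict[Subgroup, int], total: int) -> dict[Subgroup, int]:
    """Apportion ``total`` slots proportionally to ``counts`` (deterministic)."""
    if not counts or total <= 0:
        return {}
    weight = sum(counts.values())
    quotas = {k: total * v / weight for k, v in counts.items()}
    out = {k: int(q) for k, q in quotas.items()}
    short = total - sum(out.values())
    order = sorted(counts, key=lambda k: (-(quotas[k] - out[k]), k.value))
    for k in order[:short]:
        out[k] += 1
    return out


def _draw_group(
    name: Group,
    gspec: GroupSpec,
    n: int,
    rng: np.random.Generator,
    id_start: int,
    non_diagnostic: bool = False,
) -> list[PatientRecord]:
    mpap_marg = match_truncated_normal(gspec.mpap)
    z0 = rng.standard_normal(n)
    mpap = mpap_marg.ppf_of_z(z0)
    if name is Group.NO_PH:
        mpap = np.minimum(mpap, np.nextafter(25.0, 0.0))
    values: dict[str, np.ndarray] = {}
    for metric, mspec in gspec.metrics.items():
        marg = match_truncated_normal(mspec)
        rho = calibrate_latent_corr(mpap_marg, marg, mspec.corr_mpap)
        z = rho * z0 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        values[metric] = marg.ppf_of_z(z)
    lge = rng.random(n) < gspec.lge_rate
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"SYN-{id_start + i:04d}",
                group=name,
                mpap=float(mpap[i]),
                pvr=float(values["pvr"][i]) if "pvr" in values else None,
                metrics={k: float(v[i]) for k, v in values.items() if k != "pvr"},
                lge_present=bool(lge[i]),
                non_diagnostic=non_diagnostic,
            )
        )
    return records


def make_cohort(spec: CohortSpec, seed: int) -> list[PatientRecord]:
    """Draw a full synthetic cohort; identical seeds give identical cohorts.

    Membership in sub-studies (``spec.subsets``: late gadolinium enhancement,
    phase contrast, echo) is drawn without replacement per group; metrics
    outside a record's sub-studies are removed, and ``lge_present`` is None
    outside the LGE subset. PH subgroups are apportioned by largest
    remainder from ``subgroup_counts`` and assigned in shuffled order.
    ``n_non_diagnostic`` extra artefact-degraded records are appended with
    the ``non_diagnostic`` flag set; analyses drop them first.
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    next_id = 0
    by_group: dict[Group, list[PatientRecord]] = {}
    for gname in sorted(spec.groups, key=lambda g: g.value):
        gspec = spec.groups[gname]
        recs = _draw_group(gname, gspec, gspec.n, rng, next_id)
        next_id += gspec.n
        by_group[gname] = recs
        records.extend(recs)

    # sub-study membership
    subset_members: dict[str, set[str]] = {}
    for sub_name in sorted(spec.subsets):
        members: set[str] = set()
        for gname in sorted(spec.subsets[sub_name], key=lambda g: g.value):
            k = min(spec.subsets[sub_name][gname], len(by_group.get(gname, [])))
            chosen = rng.choice(len(by_group[gname]), size=k, replace=False)
            members.update(by_group[gname][i].patient_id for i in chosen)
        subset_members[sub_name] = members

    pc_metrics = {
        "pa_average_velocity", "pa_retrograde_flow", "pa_retrograde_percent",
        "pa_rac", "pa_systolic_area", "pa_diastolic_area",
    }
    echo_metrics = {"trjv", "echo_mpap"}
    for rec in records:
        if "lge" in subset_members and rec.patient_id not in subset_members["lge"]:
            rec.lge_present = None
        if "phase_contrast" in subset_members and rec.patient_id not in subset_members["phase_contrast"]:
            for m in pc_metrics:
                rec.metrics.pop(m, None)
        if "echo" in subset_members and rec.patient_id not in subset_members["echo"]:
            for m in echo_metrics:
                rec.metrics.pop(m, None)

    # PH subgroups
    ph_recs = by_group.get(Group.PH, [])
    if spec.subgroup_counts and ph_recs:
        alloc = _largest_remainder(spec.subgroup_counts, len(ph_recs))
        labels: list[Subgroup] = []
        for sg in sorted(alloc, key=lambda s: s.value):
            labels.extend([sg] * alloc[sg])
        perm = rng.permutation(len(ph_recs))
        for pos, rec_idx in enumerate(perm):
            ph_recs[rec_idx].subgroup = labels[pos]

    # artefact-degraded extras, excluded from every analysis
    if spec.n_non_diagnostic > 0:
        group_names = sorted(spec.groups, key=lambda g: g.value)
        probs = np.array([spec.groups[g].n for g in group_names], dtype=float)
        probs /= probs.sum()
        draws = rng.choice(len(group_names), size=spec.n_non_diagnostic, p=probs)
        for j, gi in enumerate(draws):
            gname = group_names[gi]
            rec = _draw_group(gname, spec.groups[gname], 1, rng, next_id, non_diagnostic=True)[0]
            next_id += 1
            records.append(rec)
    return records
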