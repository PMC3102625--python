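"""Quantitative validation: side-of-surface agreement and kappa statistics.

The validation criterion mirrors the original experiment: release particles
on one side of a tracked surface and count, at a query time, the fraction
still on their release side.  If the finite-volume flow map and the
independent RK4 tracer transport material identically, no particle ever
crosses the surface and the agreement is 100%.  The agreement percentage is
n_agree / n_released(t_query) * 100, with the denominator counting every
particle released up to the query time (frozen out-of-domain particles are
kept in the denominator and flagged).  Boundary tie rule: g = 0 counts as
inside, consistent with V(t) = {g <= 0}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError
from .field import VelocityField
from .particles import ParticleSet, ReleaseSpec, trace_particles
from .volumes import TrackedVolume

__all__ = [
    "AgreementReport",
    "particle_side",
    "agreement",
    "agreement_sensitivity",
    "cohen_kappa",
]


def particle_side(tv: TrackedVolume, points, t: float):
    """Side labels ('inside' if g <= 0 else 'outside') at world points.

    g is interpolated trilinearly in space and linearly between stored times;
    out-of-grid points are evaluated clamped and flagged.  Returns
    ``(labels, clamped)``.
    """
    vals, clamped = tv.sample(points, t)
    labels = np.where(vals <= 0.0, "inside", "outside")
    return labels, clamped


@dataclass
class AgreementReport:
    """Result of one agreement evaluation."""

    t_query: float
    n_released: int
    n_agree: int
    agreement_pct: float
    per_particle: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "t_query": self.t_query,
            "n_released": self.n_released,
            "n_agree": self.n_agree,
            "agreement_pct": self.agreement_pct,
            "n_frozen": int(self.per_particle["frozen"].sum()),
        }


def agreement(particles: ParticleSet, tv: TrackedVolume, t_query: float) -> AgreementReport:
    """Fraction of released particles still on their release side at t_query.

    The release side is the recorded sign of the volume function at the seed
    when available, else the sign of g at the seed at the release time (the
    two coincide whenever the surface has not crossed the seed region before
    release).  Frozen particles are evaluated at their frozen position.
    """
    sel = np.flatnonzero(particles.release_times <= t_query + 1e-12)
    if sel.size == 0:
        raise UndefinedRatioError(f"no particles released up to t_query={t_query}")
    pos = particles.position_at(t_query)[sel]
    side_q, clamped = particle_side(tv, pos, t_query)
    inside_q = side_q == "inside"
    if particles.release_inside is not None:
        inside_r = particles.release_inside[sel]
    else:
        inside_r = np.empty(sel.size, dtype=bool)
        for t_r in np.unique(particles.release_times[sel]):
            m = particles.release_times[sel] == t_r
            t_eval = max(t_r, float(np.min(tv.query_times)))
            vals, _ = tv.sample(particles.release_positions[sel][m], t_eval)
            inside_r[m] = vals <= 0.0
    agree = inside_q == inside_r
    per = pd.DataFrame(
        {
            "particle_id": sel,
            "release_time": particles.release_times[sel],
            "release_inside": inside_r,
            "inside_at_query": inside_q,
            "agree": agree,
            "frozen": particles.ever_left[sel],
            "clamped_eval": clamped,
        }
    )
    n_rel = int(sel.size)
    n_agree = int(agree.sum())
    return AgreementReport(
        t_query=float(t_query),
        n_released=n_rel,
        n_agree=n_agree,
        agreement_pct=100.0 * n_agree / n_rel,
        per_particle=per,
    )


def agreement_sensitivity(
    field: VelocityField,
    tv: TrackedVolume,
    release_spec: ReleaseSpec,
    counts,
    t_query: float,
    seed: int = 0,
    dt: float | None = None,
    f=None,
):
    """Re-run the agreement at several particle counts with independent seeds.

    Returns ``(table, sd)``: a DataFrame with one row per count (count,
    agreement_pct, n_released) and the standard deviation (percentage
    points, ddof=0) of the agreement across counts.
    """
    counts = list(counts)
    if len(counts) < 2:
        raise UndefinedRatioError("need at least 2 particle counts for a sensitivity sweep")
    ss = np.random.SeedSequence(seed)
    rows = []
    for child, n in zip(ss.spawn(len(counts)), counts):
        rng = np.random.default_rng(child)
        seeds, rel = release_spec.sample(int(n), rng)
        ps = trace_particles(field, seeds, rel, t_end=max(t_query, rel.max()), dt=dt, f=f)
        rep = agreement(ps, tv, t_query)
        rows.append({"count": int(n), "agreement_pct": rep.agreement_pct,
                     "n_released": rep.n_released})
    table = pd.DataFrame(rows)
    sd = float(np.std(table["agreement_pct"].to_numpy(), ddof=0))
    return table, sd


def cohen_kappa(table_a, table_b) -> float:
    """Cohen's kappa for two boolean rating tables of identical shape.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal products.  If both raters are constant and identical (p_e = 1),
    kappa is 1 by convention (flagged via a warning).
    """
    a = np.asarray(table_a).astype(bool).ravel()
    b = np.asarray(table_b).astype(bool).ravel()
    if a.shape != b.shape:
        raise UndefinedRatioError(
            f"rating tables must have the same shape, got {a.shape} vs {b.shape}"
        )
    if a.size == 0:
        raise UndefinedRatioError("empty rating tables")
    p_o = float(np.mean(a == b))
    pa, pb = float(np.mean(a)), float(np.mean(b))
    p_e = pa * pb + (1.0 - pa) * (1.0 - pb)
    if p_e >= 1.0 - 1e-15:
        import warnings

        warnings.warn("both raters constant and identical; kappa = 1 by convention")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)
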