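"""Seeded synthetic EMA cohorts with the study's sampling design.

The real cohort this emulates: 92 analyzable participants (52 who lapsed in
the first post-quit week, 40 who stayed abstinent), each carrying a mobile
phone that prompted one wake-anchored daily diary plus four random EMAs per
day over 16 waking hours for 7 days, with additional self-initiated EMAs.

Because the six risk factors are reported by proximity class (within 4 h of
the first lapse / more than 4 h before it / abstainer), items are generated
conditional on the class an EMA will eventually fall into; the ordinal items
are drawn through an :class:`OrdinalMap` so that downstream dichotomization
recovers the configured class prevalence exactly in expectation.  An optional
shared Gaussian copula factor induces positive inter-item correlation while
preserving the marginals.

Everything is driven by per-participant substreams spawned from
``master_seed``: identical :class:`SimConfig` ⇒ identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy.special import ndtr

from .ema_model import CohortTable, EmaRecord, Participant, PromptType, Arm

__all__ = [
    "SimConfig",
    "OrdinalMap",
    "map_prevalence_to_ordinal",
    "draw_item_matrix",
    "generate_cohort",
    "FACTOR_NAMES",
    "PREVALENCE_WITHIN4H",
    "PREVALENCE_OVER4H",
    "PREVALENCE_ABSTAINER",
]

#: Risk-factor order used by every prevalence vector (the study's table
#: order): urge, stress, low cessation motivation, cigarette availability,
#: recent alcohol, interacting with a smoker.
FACTOR_NAMES = ("urge", "stress", "low_motivation", "availability",
                "alcohol", "smoker_interaction")

# Group-conditional risk-factor prevalences reported for the real cohort.
PREVALENCE_WITHIN4H = (0.593, 0.411, 0.173, 0.748, 0.191, 0.336)
PREVALENCE_OVER4H = (0.491, 0.188, 0.151, 0.704, 0.189, 0.129)
PREVALENCE_ABSTAINER = (0.328, 0.259, 0.010, 0.526, 0.034, 0.121)

#: Look-ahead window (hours) defining the "imminent lapse" class during
#: generation; mirrors the analysis default.
GENERATOR_WINDOW_HOURS = 4.0

_WAKE_OFFSET_HOURS = 8.0  # waking window opens 08:00 (wake 07:30 + 30 min)


class SimConfig(BaseModel):
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: 52 lapsers + 40 abstainers,
    7 post-quit days, 5 prompted EMAs/day over a 16-hour waking window,
    self-initiated EMAs and 90% prompt compliance tuned so completed EMAs
    average ≈ 43.5 per participant, and class-conditional prevalences equal
    to the reported ones.
    """

    n_lapsers: int = Field(52, ge=0)
    n_abstainers: int = Field(40, ge=0)
    days_postquit: int = Field(7, gt=0)
    prompts_per_day: int = Field(5, gt=0)
    waking_window_hours: float = Field(16.0, gt=0)
    selfinit_rate_per_day: float = Field(1.7, ge=0)
    compliance_prob: float = Field(0.9, ge=0, le=1)
    prevalence_within4h: tuple[float, ...] = PREVALENCE_WITHIN4H
    prevalence_over4h: tuple[float, ...] = PREVALENCE_OVER4H
    prevalence_abstainer: tuple[float, ...] = PREVALENCE_ABSTAINER
    latent_correlation: float = Field(0.0, ge=0, lt=1)
    inconsistent_fraction: float = Field(0.0, ge=0, le=1)
    lapse_selfinit_prob: float = Field(0.6, ge=0, le=1)
    lapse_selfinit_lead_minutes: float = Field(120.0, gt=0)
    min_prompt_spacing_minutes: float = Field(90.0, ge=0)
    quit_date: str = "2012-03-05"
    master_seed: int = 0

    @field_validator("prevalence_within4h", "prevalence_over4h",
                     "prevalence_abstainer")
    @classmethod
    def _check_prevalences(cls, v):
        if len(v) != 6:
            raise ValueError(f"prevalence vector must have 6 entries, got {len(v)}")
        if not all(0.0 <= p <= 1.0 for p in v):
            raise ValueError("prevalences must lie in [0, 1]")
        return tuple(float(p) for p in v)


@dataclass(frozen=True)
class OrdinalMap:
    """Fixed split of probability mass across the 5 ordinal categories.

    ``category_order`` lists categories from the low to the high end of the
    latent-uniform scale, with the indicator-positive categories occupying
    the top so that a shared copula factor shifts mass into them coherently;
    ``masses`` are the corresponding probabilities (summing to 1, with
    exactly ``prevalence`` on the positive categories).
    """

    item: str
    prevalence: float
    category_order: tuple[int, ...]
    masses: tuple[float, ...]
    positive_categories: tuple[int, ...]

    def __post_init__(self):
        if abs(sum(self.masses) - 1.0) > 1e-12:
            raise ValueError("category masses must sum to 1")
        pos_mass = sum(m for c, m in zip(self.category_order, self.masses)
                       if c in self.positive_categories)
        if abs(pos_mass - self.prevalence) > 1e-12:
            raise ValueError("positive-category mass must equal prevalence")

    def sample(self, u: np.ndarray) -> np.ndarray:
        """Map latent uniforms in [0,1) to ordinal categories 1-5."""
        bounds = np.cumsum(self.masses)[:-1]
        idx = np.searchsorted(bounds, u, side="right")
        return np.asarray(self.category_order)[idx]


# Positive mass split 60/40 over ("fairly agree", "strongly agree") and
# negative mass 20/40/40 over the remaining categories; arbitrary but fixed —
# only the dichotomized mass matters downstream.
_POS_SPLIT = (0.6, 0.4)
_NEG_SPLIT = (0.2, 0.4, 0.4)


def map_prevalence_to_ordinal(p: float, item: str) -> OrdinalMap:
    """Build the ordinal distribution whose dichotomization has prevalence p.

    For agree-keyed items (urge, stress, availability) the indicator is
    response ≥ 4; for cessation motivation the indicator is response ≤ 2
    (low commitment), so the split is mirrored.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0,1], got {p}")
    q = 1.0 - p
    if item == "motivation":
        order = (5, 4, 3, 2, 1)
        positive = (1, 2)
    elif item in ("urge", "stress", "availability"):
        order = (1, 2, 3, 4, 5)
        positive = (4, 5)
    else:
        raise ValueError(f"not an ordinal item: {item!r}")
    masses = tuple(s * q for s in _NEG_SPLIT) + tuple(s * p for s in _POS_SPLIT)
    return OrdinalMap(item=item, prevalence=p, category_order=order,
                      masses=masses, positive_categories=positive)


def draw_item_matrix(prevalences, n: int, rng: np.random.Generator,
                     latent_correlation: float = 0.0) -> pd.DataFrame:
    """Draw ``n`` six-item EMA responses at the given factor prevalences.

    Returns a DataFrame with columns urge, stress, motivation, availability
    (ordinal 1-5) and interacting_smoker, alcohol_past_hour (bool).  Under
    ``latent_correlation`` ρ > 0 each item's latent normal shares a common
    factor with loading √ρ (Gaussian copula), leaving marginals intact.
    """
    prevalences = tuple(float(p) for p in prevalences)
    if len(prevalences) != 6:
        raise ValueError("prevalence vector must have 6 entries")
    rho = float(latent_correlation)
    if rho == 0.0:
        u = rng.random((n, 6))
    else:
        shared = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, 6))
        u = ndtr(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps)

    p_urge, p_stress, p_lowmot, p_avail, p_alc, p_smk = prevalences
    out = pd.DataFrame({
        "urge": map_prevalence_to_ordinal(p_urge, "urge").sample(u[:, 0]),
        "stress": map_prevalence_to_ordinal(p_stress, "stress").sample(u[:, 1]),
        "motivation": map_prevalence_to_ordinal(
            p_lowmot, "motivation").sample(u[:, 2]),
        "availability": map_prevalence_to_ordinal(
            p_avail, "availability").sample(u[:, 3]),
        "alcohol_past_hour": u[:, 4] > 1.0 - p_alc,
        "interacting_smoker": u[:, 5] > 1.0 - p_smk,
    })
    return out


def _prompt_times(day_start: pd.Timestamp, cfg: SimConfig,
                  rng: np.random.Generator) -> list[tuple[pd.Timestamp, PromptType]]:
    """Prompt schedule for one day: wake-anchored diary + random prompts
    with a minimum spacing (rejection-sampled)."""
    times = [(day_start, PromptType.DAILY_DIARY)]
    n_random = cfg.prompts_per_day - 1
    if n_random <= 0:
        return times
    gap_h = cfg.min_prompt_spacing_minutes / 60.0
    for _ in range(10_000):
        offs = np.sort(rng.random(n_random) * cfg.waking_window_hours)
        cand = np.concatenate([[0.0], offs])
        if np.all(np.diff(cand) >= gap_h):
            break
    else:  # spacing infeasible for this window; fall back to unspaced
        offs = np.sort(rng.random(n_random) * cfg.waking_window_hours)
    for h in offs:
        times.append((day_start + pd.Timedelta(hours=float(h)),
                      PromptType.RANDOM))
    return times


def _draw_lapse_time(quit_wake: pd.Timestamp, cfg: SimConfig,
                     rng: np.random.Generator) -> pd.Timestamp:
    """Uniform over the waking portions of the post-quit week, excluding the
    first ``GENERATOR_WINDOW_HOURS`` waking hours so that a pre-lapse window
    exists."""
    total = cfg.waking_window_hours * cfg.days_postquit
    if total <= GENERATOR_WINDOW_HOURS:
        raise ValueError("waking time too short to place a lapse")
    h = rng.uniform(GENERATOR_WINDOW_HOURS, total)
    day, within = divmod(h, cfg.waking_window_hours)
    return (quit_wake + pd.Timedelta(days=int(day))
            + pd.Timedelta(hours=float(within))).floor("min")


def generate_cohort(config: SimConfig) -> CohortTable:
    """Generate a seeded synthetic cohort.

    The returned :class:`CohortTable` carries generator bookkeeping in
    ``meta``: completed-record counts by eventual proximity class (for
    consistent reporters), which downstream windowing must conserve.
    """
    cfg = config
    quit_wake = (pd.Timestamp(cfg.quit_date)
                 + pd.Timedelta(hours=_WAKE_OFFSET_HOURS))
    quit_time = pd.Timestamp(cfg.quit_date)

    n_total = cfg.n_lapsers + cfg.n_abstainers
    streams = np.random.SeedSequence(cfg.master_seed).spawn(n_total)

    participants: list[Participant] = []
    records: list[EmaRecord] = []
    counts = {"within4h": 0, "over4h": 0, "abstainer": 0,
              "post_lapse": 0, "inconsistent": 0}

    for i in range(n_total):
        rng = np.random.default_rng(streams[i])
        is_lapser = i < cfg.n_lapsers
        pid = f"P{i + 1:03d}"
        arm = Arm.CM if rng.random() < 0.5 else Arm.UC
        consistent = rng.random() >= cfg.inconsistent_fraction

        lapse_time = (_draw_lapse_time(quit_wake, cfg, rng)
                      if is_lapser else None)
        participants.append(Participant(pid, arm, quit_time, lapse_time,
                                        consistent))

        # assemble the week's completed EMA times
        entries: list[tuple[pd.Timestamp, PromptType]] = []
        for d in range(cfg.days_postquit):
            day_start = quit_wake + pd.Timedelta(days=d)
            for t, ptype in _prompt_times(day_start, cfg, rng):
                if rng.random() < cfg.compliance_prob:
                    entries.append((t.floor("min"), ptype))
            n_si = rng.poisson(cfg.selfinit_rate_per_day)
            for h in rng.random(n_si) * cfg.waking_window_hours:
                entries.append(((day_start + pd.Timedelta(hours=float(h)))
                                .floor("min"), PromptType.URGE_SELFINIT))
        if is_lapser and rng.random() < cfg.lapse_selfinit_prob:
            lead = rng.uniform(0.0, cfg.lapse_selfinit_lead_minutes)
            t = (lapse_time - pd.Timedelta(minutes=float(lead))).floor("min")
            if t >= lapse_time:  # flooring may collide with the lapse instant
                t = lapse_time - pd.Timedelta(minutes=1)
            if t > quit_time:
                entries.append((t, PromptType.LAPSE_SELFINIT))
        entries.sort(key=lambda e: (e[0], e[1].value))

        # classify each EMA, then draw items from its class prevalences
        window = pd.Timedelta(hours=GENERATOR_WINDOW_HOURS)
        classes = []
        for t, _ in entries:
            if not is_lapser:
                classes.append("abstainer")
            elif t >= lapse_time:
                classes.append("post_lapse")
            elif lapse_time - t <= window:
                classes.append("within4h")
            else:
                classes.append("over4h")

        prev_by_class = {
            "abstainer": cfg.prevalence_abstainer,
            "within4h": cfg.prevalence_within4h,
            "over4h": cfg.prevalence_over4h,
            # post-lapse EMAs never enter analyses; reuse the imminent-lapse
            # state as a plausible ambient condition
            "post_lapse": cfg.prevalence_within4h,
        }
        n_rec = len(entries)
        items = pd.DataFrame(index=range(n_rec))
        for cls_name in ("abstainer", "within4h", "over4h", "post_lapse"):
            idx = [j for j, c in enumerate(classes) if c == cls_name]
            if not idx:
                continue
            block = draw_item_matrix(prev_by_class[cls_name], len(idx), rng,
                                     cfg.latent_correlation)
            for col in block.columns:
                items.loc[idx, col] = block[col].to_numpy()

        for j, ((t, ptype), cls_name) in enumerate(zip(entries, classes)):
            records.append(EmaRecord(
                pid, t, ptype,
                int(items.loc[j, "urge"]), int(items.loc[j, "stress"]),
                int(items.loc[j, "motivation"]),
                int(items.loc[j, "availability"]),
                bool(items.loc[j, "interacting_smoker"]),
                bool(items.loc[j, "alcohol_past_hour"]),
                smoked_since_last=(cls_name == "post_lapse")))
            if consistent:
                counts[cls_name] += 1
            else:
                counts["inconsistent"] += 1

    meta = {
        "n_within4h": counts["within4h"],
        "n_over4h": counts["over4h"],
        "n_abstainer": counts["abstainer"],
        "n_post_lapse": counts["post_lapse"],
        "n_inconsistent_records": counts["inconsistent"],
        "n_records": len(records),
        "master_seed": cfg.master_seed,
    }
    return CohortTable.from_records(participants, records, meta=meta)
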