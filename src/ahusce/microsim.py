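"""Individual-level microsimulation oracles.

These simulate finite cohorts of exchangeable patients through exactly the
same per-cycle transition rules as the deterministic engines and exist to
validate them: the expected-value cohort trace must agree with the
microsimulation within Monte-Carlo error.  The state-transition oracle
exploits exchangeability by drawing multinomial counts per state per cycle,
which is distributionally identical to simulating each patient separately.
The multiple-withdrawal oracle tracks each patient's own withdrawal clock.
"""

from __future__ import annotations

import numpy as np

from .cohort import N_STATES, LifeTable, cycle_death_probabilities
from .params import ModelConfig

__all__ = ["microsimulate_counts", "microsimulate_multiple_withdrawal"]


def microsimulate_counts(
    initial: np.ndarray,
    matrices: np.ndarray,
    n_individuals: int,
    seed: int,
) -> np.ndarray:
    """Simulate ``n_individuals`` through per-cycle matrices; return count trace.

    Returns an array (n_cycles + 1, n_states) of occupancy counts.
    """
    rng = np.random.default_rng(seed)
    n_cycles = matrices.shape[0]
    counts = np.zeros((n_cycles + 1, N_STATES), dtype=np.int64)
    counts[0] = rng.multinomial(n_individuals, initial)
    for t in range(n_cycles):
        nxt = np.zeros(N_STATES, dtype=np.int64)
        for s in range(N_STATES):
            c = counts[t, s]
            if c:
                nxt += rng.multinomial(c, matrices[t, s])
        counts[t + 1] = nxt
    return counts


# integer codes for the multiple-withdrawal individual simulation
_OFF02, _OFF3, _COURSE02, _COURSE3, _CKD4, _ESRD, _TRANS, _POST, _DEAD = range(9)


def microsimulate_multiple_withdrawal(
    values: dict[str, float],
    config: ModelConfig,
    table: LifeTable,
    relapse_probs: np.ndarray,
    course_cycles: int,
    n_individuals: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Patient-level simulation of the repeated-withdrawal strategy.

    Patients off treatment face the phase-specific relapse probability of
    their own current withdrawal episode; a relapse triggers a fixed-length
    re-treatment course after which they withdraw again with the clock
    reset.  Returns per-cycle aggregate occupancies and event counts needed
    to value the strategy (all divided by ``n_individuals``).
    """
    rng = np.random.default_rng(seed)
    n = config.n_cycles
    p_die_bg = cycle_death_probabilities(config, table, n)
    p_rel = np.asarray(relapse_probs[:n], dtype=float)
    prog02, prog3 = values["relapse_progression_ckd02"], values["relapse_progression_ckd3"]
    p45, p5t = values["ckd4_to_esrd"], values["esrd_to_transplant"]
    if config.advanced_progression_annual:
        p45 = 1 - (1 - p45) ** (1 / config.cycles_per_year)
        p5t = 1 - (1 - p5t) ** (1 / config.cycles_per_year)
    pfail = values["transplant_failure"]
    exc_e = values["excess_mortality_esrd"]
    exc_t = values["excess_mortality_transplant"]
    exc_p = values["excess_mortality_post_transplant"]

    state = np.full(n_individuals, _OFF02, dtype=np.int8)
    state[rng.random(n_individuals) > values["pct_ckd02"]] = _OFF3
    phase = np.zeros(n_individuals, dtype=np.int32)  # cycles since withdrawal
    course_left = np.zeros(n_individuals, dtype=np.int32)

    occ = np.zeros((n + 1, 9))
    off_phase_counts = np.zeros((n, 3))  # monitoring phase bands 0/1/2
    relapses = np.zeros(n)
    transplants = np.zeros(n)
    # phase p is in a band if its cycle ends within it: (p+1)*cycle <= bound
    month_days = 365.25 / 12
    phase_band_1 = int(np.floor(1 * month_days / config.cycle_length_days + 1e-9))
    phase_band_8 = int(np.floor(8 * month_days / config.cycle_length_days + 1e-9))

    def _occupancy(t):
        occ[t] = np.bincount(state, minlength=9) / n_individuals

    _occupancy(0)
    for t in range(n):
        s0 = state.copy()  # all transitions read the start-of-cycle state
        u = rng.random(n_individuals)
        alive = s0 != _DEAD
        # death first (background + state excess)
        p_d = np.full(n_individuals, p_die_bg[t])
        p_d[s0 == _ESRD] = np.clip(p_die_bg[t] + exc_e, 0, 1)
        p_d[s0 == _TRANS] = np.clip(p_die_bg[t] + exc_t, 0, 1)
        p_d[s0 == _POST] = np.clip(p_die_bg[t] + exc_p, 0, 1)
        dying = alive & (u < p_d)
        u2 = rng.random(n_individuals)
        u3 = rng.random(n_individuals)

        off02 = alive & ~dying & (s0 == _OFF02)
        off3 = alive & ~dying & (s0 == _OFF3)
        band = np.where(phase < phase_band_1, 0, np.where(phase < phase_band_8, 1, 2))
        for b in range(3):
            off_phase_counts[t, b] = np.sum((off02 | off3) & (band == b)) / n_individuals

        rel02 = off02 & (u2 < p_rel[phase.clip(0, n - 1)])
        rel3 = off3 & (u2 < p_rel[phase.clip(0, n - 1)])
        relapses[t] = (rel02.sum() + rel3.sum()) / n_individuals

        # relapse: progression split, then a re-treatment course (or CKD4)
        to_c02 = rel02 & (u3 >= prog02)
        to_c3 = (rel02 & (u3 < prog02)) | (rel3 & (u3 >= prog3))
        to_ckd4 = rel3 & (u3 < prog3)
        state[to_c02] = _COURSE02
        state[to_c3] = _COURSE3
        state[to_ckd4] = _CKD4
        course_left[to_c02 | to_c3] = course_cycles

        # survivors off treatment age their withdrawal clock
        stay_off = (off02 | off3) & ~(rel02 | rel3)
        phase[stay_off] += 1

        # course countdown; completion returns to off-treatment, clock reset
        on_course = alive & ~dying & ((s0 == _COURSE02) | (s0 == _COURSE3))
        course_left[on_course] -= 1
        done02 = on_course & (s0 == _COURSE02) & (course_left == 0)
        done3 = on_course & (s0 == _COURSE3) & (course_left == 0)
        state[done02] = _OFF02
        state[done3] = _OFF3
        phase[done02 | done3] = 0

        # advanced disease chain
        ckd4 = alive & ~dying & (s0 == _CKD4)
        state[ckd4 & (u2 < p45)] = _ESRD
        esrd = alive & ~dying & (s0 == _ESRD)
        new_tx = esrd & (u2 < p5t)
        state[new_tx] = _TRANS
        transplants[t] = new_tx.sum() / n_individuals
        trans = alive & ~dying & (s0 == _TRANS)
        fail = trans & (u3 < pfail)
        state[fail] = _ESRD
        state[trans & ~fail] = _POST

        state[dying] = _DEAD
        _occupancy(t + 1)

    return {
        "occupancy": occ,
        "off_phase_counts": off_phase_counts,
        "relapses": relapses,
        "transplants": transplants,
    }
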