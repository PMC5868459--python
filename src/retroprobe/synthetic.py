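"""Synthetic double-probe retrocue cohorts.

Generates trial-level data with the statistical structure the analyses
assume: four uniformly drawn item orientations per trial, a retrocue on 2/3
of trials, two sequential probes, and responses drawn from the
memory-plus-guessing mixture — with probability ``p_mem`` a von Mises draw
centred on the target (optionally shifted by an orientation-dependent bias
``β·sin(Δ)``, Δ the relative orientation of the other probed item), else a
uniform guess.

Per-trial precision coupling between the two responses is switchable:

- ``independent`` — the two responses' concentrations are fixed;
- ``shared_gain`` — a common per-trial gain multiplies both concentrations
  (good and bad trials affect both items → positive |error| correlation);
- ``resource_tradeoff`` — a per-trial share g splits a fixed resource,
  κ₁ ∝ 2g, κ₂ ∝ 2(1−g) (zero-sum sharing → negative |error| correlation).

The gain/share g is Beta(a, a) with a = (1/s − 1)/2, so ``coupling_strength``
s ∈ [0, 1) maps to Var(g) = s/4 and s = 0 recovers independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circstats import wrap_angle
from .data_model import SessionData, TrialRecord, label_responses
from .mixture import KAPPA_MAX

__all__ = [
    "DesignSpec",
    "GenerativeParams",
    "COUPLING_MODES",
    "simulate_session",
    "simulate_cohort",
    "draw_mixture_errors",
    "draw_coupled_error_pairs",
]

COUPLING_MODES = ("independent", "shared_gain", "resource_tradeoff")

_ROLES = ("cued", "uncued", "neutral")
_CELLS = tuple((role, idx) for role in _ROLES for idx in (1, 2))


@dataclass(frozen=True)
class DesignSpec:
    """Trial-count structure of one session.

    ``condition_mix`` gives per-block counts of (neutral, cued_first,
    cued_second) trials; ``order_cued_blocks`` says, per block, whether the
    retrocue also conveys probe order.
    """

    experiment: str
    n_blocks: int
    trials_per_block: int
    condition_mix: tuple[int, int, int]  # neutral, cued_first, cued_second
    order_cued_blocks: tuple[bool, ...]
    n_items: int = 4
    probes_per_trial: int = 2

    def __post_init__(self):
        if sum(self.condition_mix) != self.trials_per_block:
            raise ValueError("condition_mix must sum to trials_per_block")
        if len(self.order_cued_blocks) != self.n_blocks:
            raise ValueError("order_cued_blocks needs one flag per block")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @classmethod
    def e1(cls) -> "DesignSpec":
        # 8 blocks x 60 trials (20 neutral / 20 cued-first / 20 cued-second)
        return cls("E1", 8, 60, (20, 20, 20), (False,) * 8)

    @classmethod
    def e2(cls) -> "DesignSpec":
        # as E1 but the cue colour also announces probe order
        return cls("E2", 8, 60, (20, 20, 20), (True,) * 8)

    @classmethod
    def e2b(cls) -> "DesignSpec":
        # order conveyed and additionally blocked; trial counts as E2
        return cls("E2b", 8, 60, (20, 20, 20), (True,) * 8)

    @classmethod
    def e3(cls) -> "DesignSpec":
        # 600 trials: 100 per condition with and without the order cue
        return cls("E3", 10, 60, (20, 20, 20), (False,) * 5 + (True,) * 5)

    @classmethod
    def from_name(cls, name: str) -> "DesignSpec":
        try:
            return {"E1": cls.e1, "E2": cls.e2, "E2b": cls.e2b, "E3": cls.e3}[name]()
        except KeyError:
            raise ValueError(f"unknown experiment {name!r}; use E1, E2, E2b or E3") from None


def _cell_dict(cued, uncued, neutral, second_penalty=0.0):
    return {
        ("cued", 1): cued,
        ("cued", 2): cued - second_penalty,
        ("uncued", 1): uncued,
        ("uncued", 2): uncued - second_penalty,
        ("neutral", 1): neutral,
        ("neutral", 2): neutral - second_penalty,
    }


@dataclass(frozen=True)
class GenerativeParams:
    """Cohort-level truth for the response model, keyed by (role, response index).

    Defaults encode the qualitative retrocue findings: recall probability is
    higher for cued and lower for uncued items, slightly lower on the second
    response; precision κ is role-invariant; a repulsive bias of −5° acts
    only on the first response when the cued item is still pending
    (role uncued, response 1).
    """

    p_mem: dict = field(default_factory=lambda: _cell_dict(0.85, 0.65, 0.75, 0.05))
    kappa: dict = field(default_factory=lambda: {cell: 12.0 for cell in _CELLS})
    beta: dict = field(
        default_factory=lambda: {
            cell: (np.deg2rad(-5.0) if cell == ("uncued", 1) else 0.0) for cell in _CELLS
        }
    )
    coupling: str = "independent"
    coupling_strength: float = 0.0
    subject_sd: dict = field(
        default_factory=lambda: {"p_mem": 0.08, "kappa": 3.0, "beta": np.deg2rad(1.0)}
    )

    def __post_init__(self):
        if self.coupling not in COUPLING_MODES:
            raise ValueError(f"coupling must be one of {COUPLING_MODES}")
        if not 0.0 <= self.coupling_strength < 1.0:
            raise ValueError("coupling_strength must be in [0, 1)")
        for cell, p in self.p_mem.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_mem{cell} out of [0, 1]")
        for cell, k in self.kappa.items():
            if k < 0.0:
                raise ValueError(f"kappa{cell} must be nonnegative")

    @classmethod
    def flat(cls, p_mem: float = 0.75, kappa: float = 12.0, **kw) -> "GenerativeParams":
        """Role- and order-invariant truth (for null-effect cohorts)."""
        return cls(
            p_mem={cell: p_mem for cell in _CELLS},
            kappa={cell: kappa for cell in _CELLS},
            beta={cell: 0.0 for cell in _CELLS},
            **kw,
        )


def _coupling_shares(mode: str, strength: float, n: int, rng: np.random.Generator):
    """Per-trial resource shares (g1, g2) in (0, 1), mean 1/2 each."""
    if mode == "independent" or strength == 0.0:
        g = np.full(n, 0.5)
        return g, g.copy()
    a = (1.0 / strength - 1.0) / 2.0
    g = rng.beta(a, a, size=n)
    if mode == "shared_gain":
        return g, g.copy()
    return g, 1.0 - g  # resource_tradeoff


def draw_mixture_errors(
    n: int, p_mem: float, kappa, rng: np.random.Generator, mu=0.0
) -> np.ndarray:
    """Vectorized draw from the memory/guess mixture, wrapped to (−π, π].

    ``kappa`` and ``mu`` may be scalars or length-n arrays (per-trial
    concentration / bias shift of the memory component).
    """
    kappa = np.broadcast_to(np.asarray(kappa, float), (n,))
    mu = np.broadcast_to(np.asarray(mu, float), (n,))
    remembered = rng.random(n) < p_mem
    errors = rng.uniform(-np.pi, np.pi, size=n)
    if remembered.any():
        k = np.maximum(kappa[remembered], 1e-9)
        errors[remembered] = rng.vonmises(mu[remembered], k)
    return wrap_angle(errors)


def draw_coupled_error_pairs(
    n: int,
    p_mem: tuple[float, float],
    kappa: tuple[float, float],
    coupling: str,
    strength: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired signed errors for the two responses under a coupling regime."""
    g1, g2 = _coupling_shares(coupling, strength, n, rng)
    e1 = draw_mixture_errors(n, p_mem[0], kappa[0] * 2.0 * g1, rng)
    e2 = draw_mixture_errors(n, p_mem[1], kappa[1] * 2.0 * g2, rng)
    return e1, e2


def _perturbed(params: GenerativeParams, rng: np.random.Generator) -> GenerativeParams:
    """One subject's truth: cohort means jittered by subject_sd, then clipped."""
    sd = params.subject_sd
    p_mem = {
        c: float(np.clip(v + rng.normal(0.0, sd["p_mem"]), 0.02, 0.98))
        for c, v in params.p_mem.items()
    }
    kappa = {
        c: float(np.clip(v + rng.normal(0.0, sd["kappa"]), 0.5, KAPPA_MAX))
        for c, v in params.kappa.items()
    }
    beta = {c: float(v + rng.normal(0.0, sd["beta"])) for c, v in params.beta.items()}
    return replace(params, p_mem=p_mem, kappa=kappa, beta=beta)


def simulate_session(
    design: DesignSpec,
    params: GenerativeParams,
    seed,
    subject_id: str = "S01",
) -> SessionData:
    """Simulate one subject's session; fully reproducible from ``seed``.

    Item orientations are uniform on [0, 360); the cued item and the probed
    items are uniform over the design's legal choices; each response follows
    the mixture response model with the (role, response index) cell's
    parameters, the memory component centred on target + β·sin(Δ).
    """
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    for block in range(1, design.n_blocks + 1):
        conditions = (
            ["neutral"] * design.condition_mix[0]
            + ["cued_first"] * design.condition_mix[1]
            + ["cued_second"] * design.condition_mix[2]
        )
        rng.shuffle(conditions)
        order_cued = design.order_cued_blocks[block - 1]
        for t, condition in enumerate(conditions, start=1):
            items = rng.uniform(0.0, 360.0, size=design.n_items)
            if condition == "neutral":
                p1, p2 = rng.choice(design.n_items, size=2, replace=False) + 1
                cued = None
            else:
                cued = int(rng.integers(1, design.n_items + 1))
                other = int(rng.choice([i for i in range(1, design.n_items + 1) if i != cued]))
                p1, p2 = (cued, other) if condition == "cued_first" else (other, cued)
            rec = TrialRecord(
                subject_id=subject_id,
                experiment=design.experiment,
                block=block,
                trial=t,
                condition=condition,
                order_cued=order_cued,
                item_angles=tuple(items),
                cued_item=cued,
                probe1_item=int(p1),
                probe2_item=int(p2),
                response1_deg=None,
                response2_deg=None,
            )
            roles = label_responses(rec)
            cells = [(roles[0].role, 1), (roles[1].role, 2)]
            g1, g2 = _coupling_shares(params.coupling, params.coupling_strength, 1, rng)
            shares = (g1[0], g2[0])
            responses = []
            probes = (int(p1), int(p2))
            for k in (0, 1):
                cell = cells[k]
                target = items[probes[k] - 1]
                delta = wrap_angle(np.deg2rad(items[probes[1 - k] - 1] - target))
                mu = params.beta[cell] * np.sin(delta)
                err = draw_mixture_errors(
                    1, params.p_mem[cell], params.kappa[cell] * 2.0 * shares[k], rng, mu=mu
                )[0]
                responses.append(float(np.mod(target + np.rad2deg(err), 360.0)))
            records.append(
                replace(rec, response1_deg=responses[0], response2_deg=responses[1])
            )
    return SessionData(records=records, metadata={"experiment": design.experiment, "seed": seed})


def simulate_cohort(
    design: DesignSpec,
    params: GenerativeParams,
    n_subjects: int,
    seed,
) -> list[SessionData]:
    """Simulate a cohort with between-subject parameter variability.

    Each subject's generative truth is drawn around the cohort means with
    ``subject_sd`` (clipped to valid ranges); per-subject streams derive
    from the master seed, so the cohort is bit-reproducible.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    sessions = []
    for i, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        subj_params = _perturbed(params, rng)
        sessions.append(
            simulate_session(design, subj_params, rng.integers(2**31), subject_id=f"S{i:02d}")
        )
    return sessions
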