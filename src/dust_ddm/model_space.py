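"""The six competing diffusion-model parametrizations.

Each model fixes which starting-point and drift parameters exist and how a
trial's context — norm prompt (NONE/SAME/ONLY), social-cue configuration
(incongruent arrows, or congruent arrows pointing left/right) and the true
motion direction — maps onto a concrete parameter vector:

* ``reduced``       — one starting point, one drift magnitude (5 params)
* ``sp_reduced``    — adds congruent-left and congruent-right starting
                      points shared across norm conditions (7)
* ``sp``            — congruent-left/right starting points per norm (11)
* ``drift_reduced`` — separate drifts for incongruent vs congruent cues (6)
* ``drift``         — congruent drift per norm condition (8)
* ``spdr``          — union of the sp and drift parametrizations (14)

Threshold separation ``a``, non-decision time ``t0`` and drift variability
``sv`` are always shared across contexts.  Drift parameters are magnitudes;
the sign is set by the true stimulus direction (positive toward the upper
boundary, which codes RIGHT).  Congruent-left cues pull the starting point
below 0.5, congruent-right cues above, regardless of the stimulus.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .ddm_core import DDMParams

__all__ = [
    "Norm",
    "Social",
    "Stimulus",
    "TrialContext",
    "ModelSpec",
    "MODEL_NAMES",
    "build_model",
    "resolve_params",
    "all_contexts",
]


class Norm(str, enum.Enum):
    NONE = "NONE"
    SAME = "SAME"
    ONLY = "ONLY"


class Social(str, enum.Enum):
    INCONGRUENT = "INCONGRUENT"
    CONGRUENT_LEFT = "CONGRUENT_LEFT"
    CONGRUENT_RIGHT = "CONGRUENT_RIGHT"


class Stimulus(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


@dataclass(frozen=True)
class TrialContext:
    """Norm prompt, arrow configuration and true motion direction."""

    norm: Norm
    social: Social
    stimulus: Stimulus

    @property
    def valid(self) -> bool | None:
        """Cue validity: True/False for congruent arrows, None for dots-only."""
        if self.social is Social.INCONGRUENT:
            return None
        cued = Stimulus.LEFT if self.social is Social.CONGRUENT_LEFT else Stimulus.RIGHT
        return cued == self.stimulus


MODEL_NAMES = ("reduced", "sp_reduced", "sp", "drift_reduced", "drift", "spdr")

_NORMS = (Norm.NONE, Norm.SAME, Norm.ONLY)
_SOCIALS = (Social.INCONGRUENT, Social.CONGRUENT_LEFT, Social.CONGRUENT_RIGHT)
_STIMULI = (Stimulus.LEFT, Stimulus.RIGHT)


def all_contexts():
    """All 18 norm x social x stimulus combinations."""
    return [
        TrialContext(n, s, st) for n in _NORMS for s in _SOCIALS for st in _STIMULI
    ]


@dataclass(frozen=True)
class ModelSpec:
    """A complete map from trial context to parameter indices.

    ``param_names`` orders the flat parameter vector theta; ``param_kinds``
    labels each entry (``a``, ``w``, ``v`` or ``t0``/``sv``) so priors can be
    assigned by kind.  ``start_point_map`` / ``drift_map`` send each
    (norm, social) pair to the index of the starting-point / drift-magnitude
    parameter used on such trials (the stimulus only flips the drift sign,
    so maps do not depend on it).
    """

    name: str
    param_names: tuple[str, ...]
    param_kinds: tuple[str, ...]
    start_point_map: dict = field(repr=False)
    drift_map: dict = field(repr=False)
    idx_a: int = 0
    idx_t0: int = 0
    idx_sv: int = 0

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def context_indices(self, ctx: TrialContext) -> tuple[int, int]:
        """(starting-point index, drift-magnitude index) for a context."""
        key = (ctx.norm, ctx.social)
        return self.start_point_map[key], self.drift_map[key]


def _norm_tag(norm: Norm) -> str:
    return norm.value.lower()


def build_model(name: str) -> ModelSpec:
    """Construct one of the six model parametrizations by name."""
    name = str(name).lower()
    if name not in MODEL_NAMES:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
        )

    names: list[str] = ["a", "w_base"]
    kinds: list[str] = ["a", "w"]

    sp_keys: dict[tuple[Norm, Social], str] = {}
    dr_keys: dict[tuple[Norm, Social], str] = {}
    for norm in _NORMS:
        for social in _SOCIALS:
            sp_keys[(norm, social)] = "w_base"
            dr_keys[(norm, social)] = "v_base"

    if name in ("sp_reduced", "sp", "spdr"):
        per_norm = name in ("sp", "spdr")
        for norm in _NORMS:
            tag = f"_{_norm_tag(norm)}" if per_norm else ""
            for side, social in (
                ("l", Social.CONGRUENT_LEFT),
                ("r", Social.CONGRUENT_RIGHT),
            ):
                pname = f"w_cong{side}{tag}"
                if pname not in names:
                    names.append(pname)
                    kinds.append("w")
                sp_keys[(norm, social)] = pname

    names.append("v_base")
    kinds.append("v")
    if name in ("drift_reduced", "drift", "spdr"):
        per_norm = name in ("drift", "spdr")
        for norm in _NORMS:
            tag = f"_{_norm_tag(norm)}" if per_norm else ""
            pname = f"v_cong{tag}"
            if pname not in names:
                names.append(pname)
                kinds.append("v")
            for social in (Social.CONGRUENT_LEFT, Social.CONGRUENT_RIGHT):
                dr_keys[(norm, social)] = pname

    names += ["t0", "sv"]
    kinds += ["t0", "sv"]

    index = {n: i for i, n in enumerate(names)}
    return ModelSpec(
        name=name,
        param_names=tuple(names),
        param_kinds=tuple(kinds),
        start_point_map={k: index[v] for k, v in sp_keys.items()},
        drift_map={k: index[v] for k, v in dr_keys.items()},
        idx_a=index["a"],
        idx_t0=index["t0"],
        idx_sv=index["sv"],
    )


def resolve_params(spec: ModelSpec, theta, ctx: TrialContext) -> DDMParams:
    """Concrete diffusion parameters for one trial context.

    ``theta`` is the flat parameter vector in ``spec.param_names`` order.
    Drift magnitudes enter with positive sign for RIGHT stimuli (toward the
    upper boundary) and negative for LEFT.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_params,):
        raise ValueError(
            f"theta has length {theta.size}, model {spec.name!r} "
            f"expects {spec.n_params}"
        )
    i_w, i_v = spec.context_indices(ctx)
    sign = 1.0 if ctx.stimulus is Stimulus.RIGHT else -1.0
    return DDMParams(
        a=float(theta[spec.idx_a]),
        w=float(theta[i_w]),
        v=sign * float(theta[i_v]),
        t0=float(theta[spec.idx_t0]),
        sv=float(theta[spec.idx_sv]),
    )
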