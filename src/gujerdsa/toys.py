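"""Small analytic models used as oracles and teaching examples."""

from __future__ import annotations

import pandas as pd

from .model import GujerModel, StateVar, build_model

__all__ = ["logistic_model", "monod_batch_model", "rotation_model", "chain_model"]


def logistic_model(r_g: float = 1.0, K: float = 2.0) -> GujerModel:
    """One-state logistic growth ``dx/dt = r_g x (1 - x/K)``.

    The ramp locus is analytic: ``x = K/2`` on ``0 < x < K``.
    """
    table = pd.DataFrame(
        [{"process": "growth", "rate": "r_g*x*(1 - x/K)", "x": "1"}]
    )
    return build_model(table, {"r_g": r_g, "K": K}, name="logistic")


def monod_batch_model(
    mu_max: float = 4.0, K_s: float = 10.0, Y: float = 0.6
) -> GujerModel:
    """Closed two-state Monod batch: substrate S drives biomass X growth.

    ``S + X/Y`` is conserved.
    """
    table = pd.DataFrame(
        [
            {
                "process": "growth",
                "rate": "mu_max*X*S/(K_s + S)",
                "S": "-1/Y",
                "X": "1",
            }
        ]
    )
    meta = {"S": StateVar("S", "g COD m-3"), "X": StateVar("X", "g COD m-3")}
    return build_model(
        table, {"mu_max": mu_max, "K_s": K_s, "Y": Y}, name="monod_batch",
        state_meta=meta,
    )


def rotation_model() -> GujerModel:
    """Harmonic rotation ``dx1/dt = x2, dx2/dt = -x1`` (states may go negative)."""
    table = pd.DataFrame(
        [
            {"process": "r1", "rate": "x2", "x1": "1", "x2": ""},
            {"process": "r2", "rate": "-x1", "x1": "", "x2": "1"},
        ]
    )
    meta = {
        "x1": StateVar("x1", "a.u.", nonnegative=False),
        "x2": StateVar("x2", "a.u.", nonnegative=False),
    }
    return build_model(table, {}, name="rotation", state_meta=meta)


def chain_model(k: float = 1.0) -> GujerModel:
    """Directed chain x1 -> rate -> x2: x1 drives the rate, only x2 is fed."""
    table = pd.DataFrame(
        [{"process": "transfer", "rate": "k*x1", "x1": "", "x2": "1"}]
    )
    return build_model(table, {"k": k}, name="chain")
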