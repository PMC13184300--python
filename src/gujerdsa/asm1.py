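"""Built-in Activated Sludge Model No. 1 (ASM1) definitions.

Two variants are shipped:

``original13``
    The classical 13-state, 8-process ASM1 (Henze et al. naming: ``S_I, S_S,
    X_I, X_S, X_BH, X_BA, X_P, S_O, S_NO, S_NH, S_ND, X_ND, S_alk``).

``mbc14``
    The mass-balance-corrected variant with 14 states.  Relative to the
    original it (i) adds dinitrogen ``S_N2`` as a state so the nitrogen
    balance of anoxic heterotrophic growth closes, and (ii) adds an ammonia
    nutrient-limitation Monod factor ``S_NHx/(S_NHx + K_NH_H)`` to
    heterotrophic growth, so biomass cannot be synthesised without a nitrogen
    source.  States use the descriptive naming ``S_b, X_cb, X_h, X_a, S_O2,
    S_NOx, S_NHx, S_bN, X_cbN`` (dynamic core) plus ``S_nb, X_nb_in`` (both
    uncoupled) and ``X_nb_e, S_N2, S_alk`` (measurement-only).

Aeration enters as the actuation slot ``z_O2`` on the dissolved-oxygen state;
its time derivative is the free symbol ``zdot_O2`` (zero for piecewise
constant aeration).

Default parameters are the 20 °C values shipped in
``data/asm1_parameters_20C.csv``.
"""

from __future__ import annotations

from collections.abc import Mapping
from importlib import resources

import pandas as pd

from .model import GujerModel, StateVar, build_model, read_parameters_csv

__all__ = ["asm1_model", "default_parameters", "ASM1_VARIANTS"]

ASM1_VARIANTS = ("original13", "mbc14")

_MBC14_STATES = [
    StateVar("S_nb", "g COD m-3"),
    StateVar("S_b", "g COD m-3"),
    StateVar("X_nb_in", "g COD m-3"),
    StateVar("X_cb", "g COD m-3"),
    StateVar("X_h", "g COD m-3"),
    StateVar("X_a", "g COD m-3"),
    StateVar("X_nb_e", "g COD m-3", measurement=True),
    StateVar("S_O2", "g O2 m-3"),
    StateVar("S_NOx", "g N m-3"),
    StateVar("S_NHx", "g N m-3", target=True),
    StateVar("S_bN", "g N m-3"),
    StateVar("X_cbN", "g N m-3"),
    StateVar("S_alk", "mol m-3", measurement=True),
    StateVar("S_N2", "g N m-3", measurement=True),
]

# Gujer matrix of the mass-balance-corrected variant.  One dict per process:
# kinetic rate expression plus the structurally non-zero stoichiometric
# entries (strings over parameter names; blank cells are zero).
_MBC14_PROCESSES = [
    {
        "process": "aerobic_growth_heterotrophs",
        "rate": (
            "mu_H * (S_b/(K_S + S_b)) * (S_O2/(K_OH + S_O2))"
            " * (S_NHx/(K_NH_H + S_NHx)) * X_h"
        ),
        "S_b": "-1/Y_H",
        "X_h": "1",
        "S_O2": "(Y_H - 1)/Y_H",
        "S_NHx": "-i_XB",
        "S_alk": "-i_XB/14",
    },
    {
        "process": "anoxic_growth_heterotrophs",
        "rate": (
            "mu_H * (S_b/(K_S + S_b)) * (K_OH/(K_OH + S_O2))"
            " * (S_NOx/(K_NO + S_NOx)) * (S_NHx/(K_NH_H + S_NHx)) * eta_g * X_h"
        ),
        "S_b": "-1/Y_H",
        "X_h": "1",
        "S_NOx": "-(1 - Y_H)/(2.86*Y_H)",
        "S_N2": "(1 - Y_H)/(2.86*Y_H)",
        "S_NHx": "-i_XB",
        "S_alk": "(1 - Y_H)/(14*2.86*Y_H) - i_XB/14",
    },
    {
        "process": "aerobic_growth_autotrophs",
        "rate": "mu_A * (S_NHx/(K_NH + S_NHx)) * (S_O2/(K_OA + S_O2)) * X_a",
        "X_a": "1",
        "S_O2": "(Y_A + i_COD_NO3)/Y_A",
        "S_NOx": "1/Y_A",
        "S_NHx": "-i_XB - 1/Y_A",
        "S_alk": "-i_XB/14 - 1/(7*Y_A)",
    },
    {
        "process": "decay_heterotrophs",
        "rate": "b_H * X_h",
        "X_cb": "1 - f_P",
        "X_h": "-1",
        "X_nb_e": "f_P",
        "X_cbN": "i_XB - f_P*i_XP",
    },
    {
        "process": "decay_autotrophs",
        "rate": "b_A * X_a",
        "X_cb": "1 - f_P",
        "X_a": "-1",
        "X_nb_e": "f_P",
        "X_cbN": "i_XB - f_P*i_XP",
    },
    {
        "process": "ammonification",
        "rate": "k_a * S_bN * X_h",
        "S_NHx": "1",
        "S_bN": "-1",
        "S_alk": "1/14",
    },
    {
        "process": "hydrolysis",
        "rate": (
            "k_h * (X_cb * X_h/(K_X*X_h + X_cb))"
            " * (S_O2/(K_OH + S_O2)"
            "    + eta_h * (K_OH/(K_OH + S_O2)) * (S_NOx/(K_NO + S_NOx)))"
        ),
        "S_b": "1",
        "X_cb": "-1",
    },
    {
        "process": "hydrolysis_organic_N",
        "rate": (
            "k_h * (X_cbN * X_h/(K_X*X_h + X_cb))"
            " * (S_O2/(K_OH + S_O2)"
            "    + eta_h * (K_OH/(K_OH + S_O2)) * (S_NOx/(K_NO + S_NOx)))"
        ),
        "S_bN": "1",
        "X_cbN": "-1",
    },
]

# Original 13-state ASM1: Henze naming, no nutrient limitation, no S_N2.
_ORIG13_STATES = [
    StateVar("S_I", "g COD m-3"),
    StateVar("S_S", "g COD m-3"),
    StateVar("X_I", "g COD m-3"),
    StateVar("X_S", "g COD m-3"),
    StateVar("X_BH", "g COD m-3"),
    StateVar("X_BA", "g COD m-3"),
    StateVar("X_P", "g COD m-3", measurement=True),
    StateVar("S_O", "g O2 m-3"),
    StateVar("S_NO", "g N m-3"),
    StateVar("S_NH", "g N m-3", target=True),
    StateVar("S_ND", "g N m-3"),
    StateVar("X_ND", "g N m-3"),
    StateVar("S_alk", "mol m-3", measurement=True),
]

_ORIG13_PROCESSES = [
    {
        "process": "aerobic_growth_heterotrophs",
        "rate": "mu_H * (S_S/(K_S + S_S)) * (S_O/(K_OH + S_O)) * X_BH",
        "S_S": "-1/Y_H",
        "X_BH": "1",
        "S_O": "(Y_H - 1)/Y_H",
        "S_NH": "-i_XB",
        "S_alk": "-i_XB/14",
    },
    {
        "process": "anoxic_growth_heterotrophs",
        "rate": (
            "mu_H * (S_S/(K_S + S_S)) * (K_OH/(K_OH + S_O))"
            " * (S_NO/(K_NO + S_NO)) * eta_g * X_BH"
        ),
        "S_S": "-1/Y_H",
        "X_BH": "1",
        "S_NO": "-(1 - Y_H)/(2.86*Y_H)",
        "S_NH": "-i_XB",
        "S_alk": "(1 - Y_H)/(14*2.86*Y_H) - i_XB/14",
    },
    {
        "process": "aerobic_growth_autotrophs",
        "rate": "mu_A * (S_NH/(K_NH + S_NH)) * (S_O/(K_OA + S_O)) * X_BA",
        "X_BA": "1",
        "S_O": "(Y_A + i_COD_NO3)/Y_A",
        "S_NO": "1/Y_A",
        "S_NH": "-i_XB - 1/Y_A",
        "S_alk": "-i_XB/14 - 1/(7*Y_A)",
    },
    {
        "process": "decay_heterotrophs",
        "rate": "b_H * X_BH",
        "X_S": "1 - f_P",
        "X_BH": "-1",
        "X_P": "f_P",
        "X_ND": "i_XB - f_P*i_XP",
    },
    {
        "process": "decay_autotrophs",
        "rate": "b_A * X_BA",
        "X_S": "1 - f_P",
        "X_BA": "-1",
        "X_P": "f_P",
        "X_ND": "i_XB - f_P*i_XP",
    },
    {
        "process": "ammonification",
        "rate": "k_a * S_ND * X_BH",
        "S_NH": "1",
        "S_ND": "-1",
        "S_alk": "1/14",
    },
    {
        "process": "hydrolysis",
        "rate": (
            "k_h * (X_S * X_BH/(K_X*X_BH + X_S))"
            " * (S_O/(K_OH + S_O)"
            "    + eta_h * (K_OH/(K_OH + S_O)) * (S_NO/(K_NO + S_NO)))"
        ),
        "S_S": "1",
        "X_S": "-1",
    },
    {
        "process": "hydrolysis_organic_N",
        "rate": (
            "k_h * (X_ND * X_BH/(K_X*X_BH + X_S))"
            " * (S_O/(K_OH + S_O)"
            "    + eta_h * (K_OH/(K_OH + S_O)) * (S_NO/(K_NO + S_NO)))"
        ),
        "S_ND": "1",
        "X_ND": "-1",
    },
]


def default_parameters() -> dict[str, float]:
    """ASM1 default parameter values at 20 °C (versioned CSV in the package)."""
    with resources.as_file(
        resources.files("gujerdsa.data").joinpath("asm1_parameters_20C.csv")
    ) as path:
        return read_parameters_csv(path)


def _table(processes, states) -> pd.DataFrame:
    cols = ["process", "rate"] + [s.name for s in states]
    rows = [{c: p.get(c, "") for c in cols} for p in processes]
    return pd.DataFrame(rows, columns=cols)


def asm1_model(
    variant: str = "mbc14", parameters: Mapping[str, float] | None = None
) -> GujerModel:
    """Build a built-in ASM1 variant.

    Parameters
    ----------
    variant
        ``"original13"`` (N=13, R=8) or ``"mbc14"`` (N=14, R=8).
    parameters
        Overrides merged over :func:`default_parameters`.
    """
    if variant not in ASM1_VARIANTS:
        raise ValueError(
            f"unknown ASM1 variant {variant!r}; choose from {ASM1_VARIANTS}"
        )
    params = default_parameters()
    if parameters:
        params.update({k: float(v) for k, v in parameters.items()})
    if variant == "original13":
        states, procs, oxy = _ORIG13_STATES, _ORIG13_PROCESSES, "S_O"
    else:
        states, procs, oxy = _MBC14_STATES, _MBC14_PROCESSES, "S_O2"
    return build_model(
        _table(procs, states),
        params,
        actuation={oxy: ("z_O2", "zdot_O2")},
        name=f"asm1_{variant}",
        state_meta={s.name: s for s in states},
    )
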