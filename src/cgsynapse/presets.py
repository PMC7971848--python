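"""Built-in experiment presets.

Each preset encodes one study scenario of the co-inhibitory assembly
model: the two-species CTLA-4/B7 clustering test, affinity sweeps over
the trans/homodimer couple, PD-L1 density x cis-affinity sweeps, the
weak/strong cis kinetic comparison, the full four-species network, and
the wild-type vs cis-knockout comparison.  ``preset(name)`` returns the
scenario's base configuration at full duration (1e7 ns); sweep scenarios
additionally expose their axes through ``grid_spec(name)``.
"""

from __future__ import annotations

import numpy as np

from .analysis import GridSpec
from .model import ConfigError, SimulationConfig

__all__ = ["preset", "grid_spec", "preset_names", "scale_config", "PRESET_NOTES"]

_FULL = dict(n_steps=10_000_000, record_stride=10_000, box_x=500.0, box_y=500.0)


def _cfg(ctla4, b7, pd1, pdl1, trans_cb, dimer, trans_pp, cis, **kw):
    params = dict(_FULL)
    params.update(kw)
    return SimulationConfig(
        copy_numbers={"CTLA4_DIMER": ctla4, "B7": b7, "PD1": pd1, "PDL1": pdl1},
        affinities={
            "trans_ctla4_b7": trans_cb,
            "dimer_b7": dimer,
            "trans_pd1_pdl1": trans_pp,
            "cis_b7_pdl1": cis,
        },
        **params,
    )


def _build_presets() -> dict[str, SimulationConfig]:
    p = {}
    # two-species clustering test: 200 CTLA-4 dimers vs 200 B7, both
    # interaction energies -7 kT, 500x500 nm interface
    p["fig2"] = _cfg(200, 200, 0, 0, -7.0, -7.0, -7.0, -7.0)
    # base for the 7x7 trans x homodimer affinity sweep (0..-13 kT)
    p["fig3_grid"] = p["fig2"]
    # lower/higher surface density variants of the same sweep (bigger or
    # smaller interface at fixed copy numbers)
    p["s1_low"] = p["fig2"].replace(box_x=700.0, box_y=700.0)
    p["s1_high"] = p["fig2"].replace(box_x=300.0, box_y=300.0)
    # CTLA-4:B7 ratio variants for the 5x5 sweep (-3..-11 kT)
    p["s3_ratio_a"] = _cfg(100, 300, 0, 0, -7.0, -7.0, -7.0, -7.0)
    p["s3_ratio_b"] = p["fig2"]
    p["s3_ratio_c"] = _cfg(300, 100, 0, 0, -7.0, -7.0, -7.0, -7.0)
    # PD-L1 density x cis-affinity sweep over the clustering background
    # (trans -5, homodimer -7); base pinned at the grid midpoint
    p["fig4_grid"] = _cfg(200, 200, 0, 120, -5.0, -7.0, -7.0, -9.0)
    # same sweep under strong clustering energies
    p["s2_grid"] = _cfg(200, 200, 0, 120, -13.0, -13.0, -7.0, -9.0)
    # kinetic comparison: many PD-L1 with weak cis vs fewer with strong cis
    p["fig5_weak"] = _cfg(200, 200, 0, 180, -5.0, -7.0, -7.0, -3.0)
    p["fig5_strong"] = _cfg(200, 200, 0, 100, -5.0, -7.0, -7.0, -13.0)
    # full four-species network; PD-1/PD-L1 affinity is swept -5..-13 kT
    # around these bases (pinned at the -9 kT midpoint here)
    p["fig6_moderate"] = _cfg(200, 200, 200, 200, -7.0, -7.0, -9.0, -7.0)
    p["fig6_strong"] = _cfg(200, 200, 200, 200, -13.0, -13.0, -9.0, -13.0)
    # wild type vs cis-knockout mutant
    p["fig7_wt"] = _cfg(200, 200, 200, 200, -5.0, -7.0, -7.0, -9.0)
    p["fig7_mt"] = p["fig7_wt"].replace(disabled_rules=("cis_b7_pdl1",))
    return p


_PRESETS = _build_presets()

PRESET_NOTES = {
    "fig2": "two-species test: 200 CTLA-4 dimers + 200 B7, trans and "
            "homodimer affinities -7 kT, 500x500x20 nm, 1e7 ns",
    "fig3_grid": "7x7 sweep of CTLA-4/B7 trans and B7 homodimer affinities, "
                 "0 to -13 kT, over the fig2 system",
    "fig4_grid": "6x6 sweep of B7/PD-L1 cis affinity (-3..-13 kT, step 2) x "
                 "PD-L1 copies (20..220, step 40); trans -5 kT, dimer -7 kT",
    "fig5_weak": "180 PD-L1 with weak cis affinity (-3 kT)",
    "fig5_strong": "100 PD-L1 with strong cis affinity (-13 kT)",
    "fig6_moderate": "full network, moderate (-7 kT) background affinities; "
                     "PD-1/PD-L1 swept -5..-13 kT",
    "fig6_strong": "full network, strong (-13 kT) background affinities; "
                   "PD-1/PD-L1 swept -5..-13 kT",
    "fig7_wt": "wild type: 200 of each species; CTLA-4/B7 -5, dimer -7, "
               "PD-1/PD-L1 -7, cis -9 kT",
    "fig7_mt": "mutant: as fig7_wt with the cis interaction knocked out "
               "(association disabled)",
    "s1_low": "fig3 sweep at lower surface density (700x700 nm)",
    "s1_high": "fig3 sweep at higher surface density (300x300 nm)",
    "s2_grid": "fig4-style sweep under strong (-13 kT) clustering energies",
    "s3_ratio_a": "5x5 affinity sweep with 100 CTLA-4 dimers : 300 B7",
    "s3_ratio_b": "5x5 affinity sweep with 200 CTLA-4 dimers : 200 B7",
    "s3_ratio_c": "5x5 affinity sweep with 300 CTLA-4 dimers : 100 B7",
}

_AFF_7 = tuple(np.linspace(0.0, -13.0, 7))
_AFF_5 = tuple(float(v) for v in np.arange(-3.0, -12.0, -2.0))
_CIS_6 = tuple(float(v) for v in np.arange(-3.0, -14.0, -2.0))
_PDL1_6 = tuple(int(v) for v in np.arange(20, 221, 40))
_PP_5 = tuple(float(v) for v in np.arange(-5.0, -14.0, -2.0))

_GRIDS = {
    "fig3_grid": GridSpec(
        (("affinity:trans_ctla4_b7", _AFF_7), ("affinity:dimer_b7", _AFF_7))
    ),
    "s1_low": GridSpec(
        (("affinity:trans_ctla4_b7", _AFF_7), ("affinity:dimer_b7", _AFF_7))
    ),
    "s1_high": GridSpec(
        (("affinity:trans_ctla4_b7", _AFF_7), ("affinity:dimer_b7", _AFF_7))
    ),
    "fig4_grid": GridSpec(
        (("affinity:cis_b7_pdl1", _CIS_6), ("copies:PDL1", _PDL1_6))
    ),
    "s2_grid": GridSpec(
        (("affinity:cis_b7_pdl1", _CIS_6), ("copies:PDL1", _PDL1_6))
    ),
    "fig6_moderate": GridSpec((("affinity:trans_pd1_pdl1", _PP_5),)),
    "fig6_strong": GridSpec((("affinity:trans_pd1_pdl1", _PP_5),)),
    "s3_ratio_a": GridSpec(
        (("affinity:trans_ctla4_b7", _AFF_5), ("affinity:dimer_b7", _AFF_5))
    ),
    "s3_ratio_b": GridSpec(
        (("affinity:trans_ctla4_b7", _AFF_5), ("affinity:dimer_b7", _AFF_5))
    ),
    "s3_ratio_c": GridSpec(
        (("affinity:trans_ctla4_b7", _AFF_5), ("affinity:dimer_b7", _AFF_5))
    ),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> SimulationConfig:
    """Return the named scenario's base configuration."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; valid presets: {', '.join(preset_names())}"
        ) from None


def grid_spec(name: str) -> GridSpec:
    """Return the sweep axes of a grid scenario."""
    preset(name)  # validates the name
    try:
        return _GRIDS[name]
    except KeyError:
        raise ConfigError(f"preset {name!r} is not a sweep scenario") from None


def scale_config(config: SimulationConfig, scale: float) -> SimulationConfig:
    """Shorten a run proportionally (scaled-down mode).

    Divides ``n_steps`` and ``record_stride`` by ``scale`` keeping at
    least one recorded sample per run.
    """
    if scale <= 0:
        raise ConfigError("scale must be positive")
    n = max(int(config.n_steps / scale), 1)
    stride = max(int(config.record_stride / scale), 1)
    stride = min(stride, n)
    return config.replace(n_steps=n, record_stride=stride)
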