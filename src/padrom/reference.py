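"""Published summary tables of the nine-player reference study.

Condition means +- SD, repeated-measures ANOVA F, Greenhouse-Geisser p and
partial eta-squared for shoulder/elbow ROM under the six pad conditions, as
reported by the reference study: nine static single-DOF tasks, the wrist
shot (SI-SR) and the slap shot (SI-ST, ST-SR).  These tables seed the
synthetic generator's restriction factors and drive the derived descriptive
quantities (mean reductions, mean percent limitations, averaged effect
sizes).

Two control-condition cells are reconstructed rather than copied: the
published static table swapped the elbow-flexion and shoulder external
rotation control means (the reported per-pad percent limitations pin them to
138.6 deg and 70.7 deg respectively), and one slap-shot SD (left shoulder
add/abd, IBX) is a typo corrected from 60.9 to 6.9.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rom import CONDITIONS, PAD_CONDITIONS, restriction_percent

__all__ = [
    "static_table",
    "wrist_table",
    "slap_table",
    "mean_pad_rom",
    "mean_pad_reduction",
    "mean_percent_limitation",
    "static_mean_partial_eta_sq",
    "left_elbow_dynamic_mean_eta_sq",
    "forearm_mean_eta_sq",
    "static_restriction_factors",
    "dynamic_restriction_factors",
]

_COLS = [f"{c}_{s}" for c in CONDITIONS for s in ("mean", "sd")] + ["p", "F", "eta_sq"]

# rows: cond1 mean, sd, ..., cond6 mean, sd, p (upper bound when censored), F, eta_p^2
_STATIC_ROWS = {
    "sho_flex":    [167.6, 4.5, 150.9, 11.8, 151.7, 14.2, 150.6, 10.6, 147.6, 10.3, 153.0, 8.3, 0.01, 7.362, 0.479],
    "sho_ext":     [46.2, 7.4, 39.1, 10.5, 41.8, 13.0, 38.1, 9.9, 35.7, 10.6, 39.5, 8.7, 0.013, 3.345, 0.295],
    "sho_add":     [45.7, 12.2, 41.1, 8.5, 41.7, 11.7, 36.3, 11.0, 38.3, 15.2, 36.4, 12.0, 0.016, 3.152, 0.259],
    "sho_abd":     [166.2, 7.7, 154.9, 7.6, 152.2, 7.7, 143.0, 15.6, 141.8, 19.2, 152.9, 5.8, 0.01, 6.653, 0.454],
    "sho_int_rot": [70.7, 5.7, 65.8, 7.6, 63.9, 9.1, 56.5, 7.7, 57.5, 7.8, 59.7, 9.7, 0.01, 9.466, 0.542],
    # control mean reconstructed (see module docstring)
    "sho_ext_rot": [70.7, 4.4, 64.9, 6.1, 60.0, 13.5, 56.9, 9.4, 60.3, 10.7, 59.1, 5.0, 0.01, 4.378, 0.354],
    # control mean reconstructed (see module docstring)
    "elb_flex":    [138.6, 9.7, 100.9, 19.7, 111.2, 18.1, 115.3, 12.7, 105.1, 23.0, 105.5, 18.7, 0.01, 10.622, 0.570],
    "forearm_pro": [77.7, 9.7, 65.1, 14.0, 66.2, 12.9, 64.3, 13.4, 65.0, 13.7, 62.6, 9.6, 0.035, 3.651, 0.313],
    "forearm_sup": [74.6, 8.6, 65.1, 13.2, 70.1, 10.2, 67.2, 12.7, 64.3, 16.2, 64.8, 14.1, 0.017, 3.175, 0.284],
}

_WRIST_ROWS = {
    "sho_flex_ext_l":    [26.7, 8.5, 19.7, 4.2, 18.7, 5.9, 20.8, 7.6, 24.8, 7.4, 23.7, 8.3, 0.011, 3.473, 0.303],
    "sho_add_abd_l":     [15.6, 7.0, 14.8, 4.8, 14.4, 6.7, 13.2, 5.1, 14.4, 6.0, 14.1, 6.5, 0.847, 0.398, 0.047],
    "sho_rot_l":         [33.9, 16.4, 32.2, 15.2, 31.8, 19.1, 31.1, 17.7, 33.7, 16.4, 30.3, 16.2, 0.484, 0.910, 0.102],
    "sho_flex_ext_r":    [38.1, 11.7, 28.7, 8.0, 26.9, 9.1, 27.6, 6.0, 30.5, 8.8, 29.0, 8.0, 0.048, 2.475, 0.236],
    "sho_add_abd_r":     [25.6, 12.0, 24.8, 11.1, 21.9, 8.4, 25.7, 9.6, 23.7, 9.8, 25.3, 10.8, 0.334, 1.177, 0.144],
    "sho_rot_r":         [29.5, 19.2, 26.7, 19.1, 27.5, 17.5, 24.8, 11.9, 29.9, 18.7, 30.3, 15.3, 0.037, 2.655, 0.228],
    "elb_flex_l":        [29.4, 13.3, 18.3, 7.1, 20.6, 6.2, 19.6, 13.2, 16.8, 8.1, 25.1, 12.1, 0.020, 4.500, 0.360],
    "forearm_pro_sup_l": [16.5, 13.8, 14.3, 8.5, 16.0, 8.9, 14.9, 8.8, 13.0, 6.8, 13.6, 7.3, 0.363, 1.125, 0.123],
    "elb_flex_r":        [14.3, 4.8, 13.4, 4.5, 12.8, 2.2, 12.4, 3.3, 14.7, 3.2, 14.7, 4.2, 0.306, 1.275, 0.137],
    "forearm_pro_sup_r": [10.8, 4.5, 9.9, 4.0, 10.1, 5.7, 11.5, 4.6, 10.5, 4.4, 9.8, 4.8, 0.867, 0.279, 0.034],
}

_SLAP_ROWS = {
    ("si_st", "sho_flex_ext_l"):    [41.5, 24.0, 38.1, 26.8, 35.3, 21.8, 38.0, 22.2, 35.5, 25.0, 41.2, 19.5, 0.354, 1.143, 0.125],
    ("si_st", "sho_add_abd_l"):     [23.7, 7.7, 23.2, 7.6, 22.7, 5.7, 19.9, 5.3, 23.3, 7.0, 20.8, 6.9, 0.129, 1.830, 0.186],
    ("si_st", "sho_rot_l"):         [59.7, 21.6, 60.2, 17.9, 51.5, 11.4, 58.2, 23.8, 50.8, 17.9, 56.5, 20.9, 0.453, 0.885, 0.100],
    ("si_st", "sho_flex_ext_r"):    [23.5, 8.5, 22.4, 10.4, 21.2, 5.3, 21.0, 8.3, 18.0, 6.9, 23.1, 8.7, 0.037, 2.642, 0.248],
    ("si_st", "sho_add_abd_r"):     [25.0, 6.4, 23.8, 6.4, 25.3, 6.7, 23.6, 9.2, 22.3, 5.0, 21.9, 5.1, 0.352, 1.148, 0.125],
    ("si_st", "sho_rot_r"):         [35.4, 10.5, 36.0, 10.1, 31.8, 9.2, 26.5, 8.8, 26.6, 7.2, 29.4, 11.7, 0.014, 3.291, 0.291],
    ("si_st", "elb_flex_l"):        [28.6, 14.4, 25.4, 13.3, 21.6, 15.5, 20.7, 15.1, 20.6, 13.6, 17.7, 14.1, 0.01, 4.723, 0.371],
    ("si_st", "forearm_pro_sup_l"): [18.9, 8.2, 14.9, 6.5, 14.1, 6.1, 16.0, 5.5, 12.2, 3.0, 16.6, 6.0, 0.021, 3.011, 0.273],
    ("si_st", "elb_flex_r"):        [34.6, 15.8, 30.8, 14.2, 34.0, 18.3, 34.9, 19.5, 33.3, 16.9, 34.3, 17.1, 0.545, 0.690, 0.079],
    ("si_st", "forearm_pro_sup_r"): [20.3, 9.7, 18.4, 7.4, 20.1, 6.9, 21.1, 11.1, 20.2, 10.8, 19.4, 5.9, 0.835, 0.193, 0.024],
    ("st_sr", "sho_flex_ext_l"):    [47.3, 21.4, 38.4, 20.6, 43.7, 18.8, 43.7, 18.9, 43.1, 21.5, 45.0, 21.7, 0.151, 2.174, 0.214],
    ("st_sr", "sho_add_abd_l"):     [26.4, 9.4, 26.1, 9.2, 24.1, 8.4, 26.4, 11.1, 25.2, 10.7, 24.7, 8.4, 0.851, 0.393, 0.047],
    ("st_sr", "sho_rot_l"):         [52.6, 17.8, 51.0, 13.1, 46.4, 6.8, 45.3, 14.1, 41.1, 9.2, 47.3, 16.2, 0.050, 2.445, 0.234],
    ("st_sr", "sho_flex_ext_r"):    [28.6, 14.1, 29.0, 14.1, 26.8, 12.7, 28.6, 10.2, 23.6, 8.5, 25.4, 14.0, 0.465, 0.944, 0.119],
    ("st_sr", "sho_add_abd_r"):     [29.2, 8.9, 23.6, 5.1, 24.2, 3.1, 23.8, 5.8, 21.7, 5.7, 23.8, 5.7, 0.043, 2.543, 0.241],
    ("st_sr", "sho_rot_r"):         [51.5, 21.1, 48.3, 21.5, 49.5, 21.3, 39.0, 21.6, 46.5, 16.9, 39.1, 20.6, 0.018, 3.175, 0.312],
    ("st_sr", "elb_flex_l"):        [26.1, 10.6, 20.4, 7.1, 23.0, 10.7, 19.7, 14.4, 17.4, 10.6, 19.3, 8.5, 0.01, 3.576, 0.309],
    ("st_sr", "forearm_pro_sup_l"): [17.9, 7.7, 16.0, 7.4, 14.8, 5.7, 18.7, 10.0, 14.6, 5.9, 18.1, 10.5, 0.355, 1.129, 0.158],
    ("st_sr", "elb_flex_r"):        [43.4, 13.6, 37.2, 18.9, 43.3, 22.3, 41.9, 20.2, 42.9, 22.5, 40.2, 18.9, 0.422, 0.922, 0.103],
    ("st_sr", "forearm_pro_sup_r"): [24.4, 12.8, 19.3, 7.8, 24.1, 4.9, 22.3, 6.3, 24.1, 6.6, 21.8, 7.5, 0.571, 0.778, 0.089],
}


def _build(rows: dict, index_names) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_COLS)
    if isinstance(next(iter(rows)), tuple):
        df.index = pd.MultiIndex.from_tuples(df.index, names=index_names)
    else:
        df.index.name = index_names
    return df


def static_table() -> pd.DataFrame:
    """Static-task summary: one row per task."""
    return _build(_STATIC_ROWS, "task")


def wrist_table() -> pd.DataFrame:
    """Wrist-shot (SI-SR) summary: one row per joint plane."""
    return _build(_WRIST_ROWS, "joint_plane")


def slap_table() -> pd.DataFrame:
    """Slap-shot summary: one row per (phase, joint plane)."""
    return _build(_SLAP_ROWS, ["phase", "joint_plane"])


# ----------------------------------------------------------- derived values


def _means(table: pd.DataFrame, row) -> tuple[float, np.ndarray]:
    control = float(table.loc[row, "no_pads_mean"])
    pads = np.array([table.loc[row, f"{c}_mean"] for c in PAD_CONDITIONS], dtype=float)
    return control, pads


def mean_pad_rom(table: pd.DataFrame, row) -> float:
    """Mean ROM over the five pad conditions for one table row."""
    _, pads = _means(table, row)
    return float(pads.mean())


def mean_pad_reduction(table: pd.DataFrame, row) -> float:
    """Control mean minus the mean over the five pad conditions, degrees."""
    control, pads = _means(table, row)
    return control - float(pads.mean())


def mean_percent_limitation(table: pd.DataFrame, row) -> float:
    """Mean percent ROM limitation over the five pad conditions."""
    control, pads = _means(table, row)
    return float(np.mean([restriction_percent(control, p) for p in pads]))


def static_mean_partial_eta_sq() -> float:
    """Average effect size over the nine static tasks."""
    return float(static_table()["eta_sq"].mean())


def left_elbow_dynamic_mean_eta_sq() -> float:
    """Average effect size for left elbow flexion across the three shot phases."""
    etas = [
        wrist_table().loc["elb_flex_l", "eta_sq"],
        slap_table().loc[("si_st", "elb_flex_l"), "eta_sq"],
        slap_table().loc[("st_sr", "elb_flex_l"), "eta_sq"],
    ]
    return float(np.mean(etas))


def forearm_mean_eta_sq() -> float:
    """Average effect size of the static forearm pronation/supination tasks."""
    table = static_table()
    return float(np.mean([table.loc["forearm_pro", "eta_sq"], table.loc["forearm_sup", "eta_sq"]]))


# -------------------------------------------------- generator seeding ratios


def static_restriction_factors() -> dict[tuple[str, str], float]:
    """Pad/control ROM ratios per (condition, static task), clipped to (0, 1]."""
    table = static_table()
    factors = {}
    for task in table.index:
        control = float(table.loc[task, "no_pads_mean"])
        factors[("no_pads", task)] = 1.0
        for cond in PAD_CONDITIONS:
            ratio = float(table.loc[task, f"{cond}_mean"]) / control
            factors[(cond, task)] = min(ratio, 1.0)
    return factors


def dynamic_restriction_factors() -> dict[tuple[str, str, str], float]:
    """Pad/control ratios per (condition, phase, joint plane), clipped to (0, 1]."""
    factors = {}
    for phase, table in [("si_sr", wrist_table())] + [
        (ph, slap_table().xs(ph, level="phase")) for ph in ("si_st", "st_sr")
    ]:
        for plane in table.index:
            control = float(table.loc[plane, "no_pads_mean"])
            factors[("no_pads", phase, plane)] = 1.0
            for cond in PAD_CONDITIONS:
                ratio = float(table.loc[plane, f"{cond}_mean"]) / control
                factors[(cond, phase, plane)] = min(ratio, 1.0)
    return factors
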