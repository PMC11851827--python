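"""Two-way repeated-measures ANOVA (Emotion × Mouth) with η² effect sizes.

The design is fully within-participant: 3 emotion levels × 2 mouth
levels, one amplitude per participant per cell.  The classical
sums-of-squares decomposition has seven sources —

    Participant, Emotion, Participant(Emotion), Mouth,
    Participant(Mouth), Emotion:Mouth, Participant(Emotion:Mouth)

— and each fixed effect is tested against its own participant-interaction
error term (F = MS_effect / MS_Participant(effect), df = (2, 2(n−1)),
(1, n−1) and (2, 2(n−1)) respectively).

Effect sizes: ``eta2`` is SS_effect divided by the sum of all seven SS
rows (the variant that reproduces published tables of this design even
when they are labelled "partial"); ``eta2_partial`` is the textbook
partial form SS_effect / (SS_effect + SS_error).  Both are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import EMOTIONS, MOUTHS

#: Row order of the ANOVA table.
ROW_ORDER = [
    "Participant",
    "Emotion",
    "Participant(Emotion)",
    "Mouth",
    "Participant(Mouth)",
    "Emotion:Mouth",
    "Participant(Emotion:Mouth)",
]

#: Error term matched to each fixed effect.
ERROR_TERM = {
    "Emotion": "Participant(Emotion)",
    "Mouth": "Participant(Mouth)",
    "Emotion:Mouth": "Participant(Emotion:Mouth)",
}


def _validate_table(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    required = {"participant", "emotion", "mouth", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"peak table missing column(s): {sorted(missing)}")
    participants = table["participant"].unique()
    if len(participants) < 3:
        raise ValueError(f"need at least 3 participants, got {len(participants)}")
    counts = table.groupby(["participant", "emotion", "mouth"], observed=True).size()
    for pid in participants:
        for e in EMOTIONS:
            for m in MOUTHS:
                if (pid, e, m) not in counts.index:
                    raise ValueError(f"participant {pid!r} is missing cell ({e!r}, {m!r})")
                if counts.loc[(pid, e, m)] != 1:
                    raise ValueError(f"participant {pid!r} has duplicate cell ({e!r}, {m!r})")
    return table


def ranova_3x2(table: pd.DataFrame, value_col: str = "amplitude_uv") -> pd.DataFrame:
    """Classical within-subject 3 × 2 ANOVA on a tidy participant × cell table.

    ``table`` needs columns participant, emotion, mouth and ``value_col``
    (one row per participant per cell, complete and balanced).  Returns a
    DataFrame indexed by :data:`ROW_ORDER` with columns df, SS, MS, F, p,
    eta2, eta2_partial (F/p/η² only on fixed-effect rows).
    """
    table = _validate_table(table, value_col)
    wide = table.pivot_table(
        index="participant", columns=["emotion", "mouth"], values=value_col, observed=True
    )
    y = wide.to_numpy()  # participants × 6, columns (emotion, mouth) sorted
    n = y.shape[0]
    a, b = len(EMOTIONS), len(MOUTHS)
    cells = y.reshape(n, a, b)

    gm = cells.mean()
    m_s = cells.mean(axis=(1, 2))            # participant means
    m_e = cells.mean(axis=(0, 2))            # emotion means
    m_m = cells.mean(axis=(0, 1))            # mouth means
    m_se = cells.mean(axis=2)                # participant × emotion
    m_sm = cells.mean(axis=1)                # participant × mouth
    m_em = cells.mean(axis=0)                # emotion × mouth

    ss = {}
    ss["Participant"] = a * b * np.sum((m_s - gm) ** 2)
    ss["Emotion"] = n * b * np.sum((m_e - gm) ** 2)
    ss["Mouth"] = n * a * np.sum((m_m - gm) ** 2)
    ss["Participant(Emotion)"] = b * np.sum(
        (m_se - m_s[:, None] - m_e[None, :] + gm) ** 2
    )
    ss["Participant(Mouth)"] = a * np.sum(
        (m_sm - m_s[:, None] - m_m[None, :] + gm) ** 2
    )
    ss["Emotion:Mouth"] = n * np.sum(
        (m_em - m_e[:, None] - m_m[None, :] + gm) ** 2
    )
    resid = (
        cells
        - m_se[:, :, None]
        - m_sm[:, None, :]
        - m_em[None, :, :]
        + m_s[:, None, None]
        + m_e[None, :, None]
        + m_m[None, None, :]
        - gm
    )
    ss["Participant(Emotion:Mouth)"] = np.sum(resid**2)

    df = {
        "Participant": n - 1,
        "Emotion": a - 1,
        "Participant(Emotion)": (n - 1) * (a - 1),
        "Mouth": b - 1,
        "Participant(Mouth)": (n - 1) * (b - 1),
        "Emotion:Mouth": (a - 1) * (b - 1),
        "Participant(Emotion:Mouth)": (n - 1) * (a - 1) * (b - 1),
    }
    return anova_from_ss({k: (df[k], ss[k]) for k in ROW_ORDER})


def anova_from_ss(ss_table: dict[str, tuple[int, float]]) -> pd.DataFrame:
    """Finish an ANOVA table from its (df, SS) decomposition.

    ``ss_table`` maps each of the seven :data:`ROW_ORDER` sources to
    ``(df, SS)``.  MS, F, p and both η² variants are (re)computed from
    those values, which makes the function usable both on fresh
    decompositions and on published SS columns treated as worked examples.
    """
    missing = [k for k in ROW_ORDER if k not in ss_table]
    if missing:
        raise ValueError(f"missing ANOVA source(s): {missing}")
    rows = {}
    ss_total = float(sum(ss for _, ss in ss_table.values()))
    for name in ROW_ORDER:
        dof, ss = ss_table[name]
        rows[name] = {"df": int(dof), "SS": float(ss), "MS": float(ss) / dof}
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(ROW_ORDER)
    for col in ("F", "p", "eta2", "eta2_partial"):
        out[col] = np.nan
    for effect, err in ERROR_TERM.items():
        ms_eff, ms_err = out.loc[effect, "MS"], out.loc[err, "MS"]
        # zero effect variance: F = 0 by convention (covers the 0/0 case)
        f = 0.0 if ms_eff == 0 else ms_eff / ms_err
        out.loc[effect, "F"] = f
        out.loc[effect, "p"] = st.f.sf(f, out.loc[effect, "df"], out.loc[err, "df"])
        out.loc[effect, "eta2"] = out.loc[effect, "SS"] / ss_total if ss_total else 0.0
        denom = out.loc[effect, "SS"] + out.loc[err, "SS"]
        out.loc[effect, "eta2_partial"] = out.loc[effect, "SS"] / denom if denom else 0.0
    out.index.name = "Effect"
    return out


def eta_squared(anova: pd.DataFrame, effect: str, kind: str = "total") -> float:
    """Effect size for one fixed effect from a finished ANOVA table.

    ``kind='total'`` divides SS_effect by the sum of all seven SS rows
    (the published-table-matching default); ``kind='partial'`` uses
    SS_effect / (SS_effect + SS_error).
    """
    if effect not in ERROR_TERM:
        raise ValueError(f"unknown effect {effect!r}; expected one of {list(ERROR_TERM)}")
    if kind == "total":
        return float(anova.loc[effect, "SS"] / anova["SS"].sum())
    if kind == "partial":
        err = ERROR_TERM[effect]
        return float(anova.loc[effect, "SS"] / (anova.loc[effect, "SS"] + anova.loc[err, "SS"]))
    raise ValueError(f"unknown eta-squared kind {kind!r}")


def greenhouse_geisser_epsilon(table: pd.DataFrame, value_col: str = "amplitude_uv") -> float:
    """Greenhouse–Geisser ε for the 3-level emotion factor (on emotion means).

    Provided for sphericity-sensitive reporting; the default tables apply
    no correction.
    """
    table = _validate_table(table, value_col)
    wide = (
        table.groupby(["participant", "emotion"], observed=True)[value_col]
        .mean()
        .unstack("emotion")
        .to_numpy()
    )
    s = np.cov(wide, rowvar=False)
    k = s.shape[0]
    mean_diag = np.trace(s) / k
    num = (k * (mean_diag - s.mean())) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=0) ** 2) + k**2 * s.mean() ** 2)
    return float(num / den)


def fit_both_components(
    p100_table: pd.DataFrame, n170_table: pd.DataFrame, value_col: str = "amplitude_uv"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA tables for the P100 and N170 amplitude tables together.

    Both inputs must list the same participants in the same order
    (cell-wise tables as produced by :func:`erpface.erp.peak_table`).
    """
    p_ids = list(p100_table["participant"].drop_duplicates())
    n_ids = list(n170_table["participant"].drop_duplicates())
    if p_ids != n_ids:
        raise ValueError("participant sets/order differ between the two peak tables")
    return ranova_3x2(p100_table, value_col), ranova_3x2(n170_table, value_col)
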