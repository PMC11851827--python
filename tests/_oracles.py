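"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use plain loops and explicit marginal means so they
share no code path with the package.
"""

import numpy as np
import pandas as pd
import scipy.stats as st


def bruteforce_rm_anova(table: pd.DataFrame, value_col: str = "amplitude_uv") -> dict:
    """Sums of squares for the 3 × 2 within-subject design via explicit loops."""
    participants = sorted(table["participant"].unique())
    emotions = sorted(table["emotion"].unique())
    mouths = sorted(table["mouth"].unique())
    val = {
        (r["participant"], r["emotion"], r["mouth"]): r[value_col]
        for _, r in table.iterrows()
    }
    n, a, b = len(participants), len(emotions), len(mouths)
    gm = sum(val.values()) / (n * a * b)

    def mean_over(keys):
        return sum(val[k] for k in keys) / len(keys)

    m_s = {s: mean_over([(s, e, m) for e in emotions for m in mouths]) for s in participants}
    m_e = {e: mean_over([(s, e, m) for s in participants for m in mouths]) for e in emotions}
    m_m = {m: mean_over([(s, e, m) for s in participants for e in emotions]) for m in mouths}
    m_se = {(s, e): mean_over([(s, e, m) for m in mouths]) for s in participants for e in emotions}
    m_sm = {(s, m): mean_over([(s, e, m) for e in emotions]) for s in participants for m in mouths}
    m_em = {(e, m): mean_over([(s, e, m) for s in participants]) for e in emotions for m in mouths}

    ss = {
        "Participant": a * b * sum((m_s[s] - gm) ** 2 for s in participants),
        "Emotion": n * b * sum((m_e[e] - gm) ** 2 for e in emotions),
        "Mouth": n * a * sum((m_m[m] - gm) ** 2 for m in mouths),
        "Participant(Emotion)": b
        * sum((m_se[s, e] - m_s[s] - m_e[e] + gm) ** 2 for s in participants for e in emotions),
        "Participant(Mouth)": a
        * sum((m_sm[s, m] - m_s[s] - m_m[m] + gm) ** 2 for s in participants for m in mouths),
        "Emotion:Mouth": n
        * sum((m_em[e, m] - m_e[e] - m_m[m] + gm) ** 2 for e in emotions for m in mouths),
    }
    ss["Participant(Emotion:Mouth)"] = sum(
        (
            val[s, e, m]
            - m_se[s, e]
            - m_sm[s, m]
            - m_em[e, m]
            + m_s[s]
            + m_e[e]
            + m_m[m]
            - gm
        )
        ** 2
        for s in participants
        for e in emotions
        for m in mouths
    )
    ss["total_about_grand_mean"] = sum((v - gm) ** 2 for v in val.values())
    return ss


def paired_ttest_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test via scipy on per-participant values."""
    res = st.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
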