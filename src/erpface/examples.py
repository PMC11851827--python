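"""Worked-example ANOVA decompositions for a 42-participant 3 × 2 design.

These are published-style (df, SS) columns for the seven sources of the
fully within-subject Emotion × Mouth ANOVA on P100 and N170 amplitudes,
used as fixed inputs in the documentation and tests to exercise the table
arithmetic (MS, F, p, η²) in :func:`erpface.anova.anova_from_ss` — the
quantities a reader can recompute from a printed SS column alone.
"""

#: P100 amplitude ANOVA: source -> (df, SS), n = 42 participants.
P100_ANOVA_SS = {
    "Participant": (41, 1118.631),
    "Emotion": (2, 0.8),
    "Participant(Emotion)": (82, 73.676),
    "Mouth": (1, 0.655),
    "Participant(Mouth)": (41, 38.447),
    "Emotion:Mouth": (2, 5.995),
    "Participant(Emotion:Mouth)": (82, 76.496),
}

#: N170 amplitude ANOVA: source -> (df, SS), n = 42 participants.
N170_ANOVA_SS = {
    "Participant": (41, 2530.883),
    "Emotion": (2, 4.322),
    "Participant(Emotion)": (82, 60.409),
    "Mouth": (1, 6.93),
    "Participant(Mouth)": (41, 28.322),
    "Emotion:Mouth": (2, 0.173),
    "Participant(Emotion:Mouth)": (82, 44.777),
}
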