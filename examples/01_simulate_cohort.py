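"""Generate a small synthetic cohort and inspect its structure.

Builds control-like (TD) and patient-like (FEP) sessions with the paradigm's
block structure (24 blocks, 6 per valence x gaze condition) and native
sampling rates, then prints the shapes and the planted clinical scores.
"""

from neurotraj import Modality, SimulationConfig, generate_cohort

config = SimulationConfig(n_td=2, n_fep=2, seed=0)
cohort = generate_cohort(config)

for session in cohort:
    eeg = session.blocks[Modality.EEG][0]
    fnirs = session.blocks[Modality.FNIRS][0]
    print(
        f"{session.subject_id:8s} group={session.group.value:3s} "
        f"EEG {eeg.data.shape} @ {eeg.sampling_rate:g} Hz | "
        f"fNIRS {fnirs.data.shape} @ {fnirs.sampling_rate:g} Hz | "
        f"GAF={session.gaf:5.1f} PANSS+={session.panss_pos:5.1f}"
    )

# Shapes follow the paradigm arithmetic: a 30-s block holds
# round(256 * 30) = 7680 EEG samples and round(8.13 * 30) = 244 fNIRS samples.
# TD controls carry NaN clinical scores (they are not scored); FEP scores are
# linked to each subject's planted switch-transient amplitude.
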