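"""Electrode montage constants (10/20 extended labels).

The acquisition montage has 32 channels; calibration uses a 21-channel
fronto-central/parietal subset covering the sensorimotor strip.
"""

# 32-channel acquisition montage (10/20 extended).
CHANNELS_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "T8", "CP3", "CPz", "CP4", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
)

# 21-channel calibration subset: frontal, fronto-central, central,
# centro-parietal, parietal and parieto-occipital rows over motor cortex.
CALIBRATION_21 = (
    "F3", "Fz", "F4",
    "FC3", "FCz", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CPz", "CP4",
    "P3", "Pz", "P4",
    "PO3", "PO4",
)

# Contralateral sensorimotor channel groups carrying class-specific ERD:
# left-hand imagery desynchronizes the right hemisphere, right-hand the
# left hemisphere, feet the midline.  Relax (X) has no ERD.
CLASS_CHANNEL_GROUPS = {
    "L": ("C4", "CP4", "FC4"),
    "R": ("C3", "CP3", "FC3"),
    "F": ("Cz", "CPz", "FCz"),
}
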