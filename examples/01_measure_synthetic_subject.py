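"""Measure the cerebral torque of one synthetic subject with known ground truth.

Builds a mirror-symmetric pair of hemisphere surfaces, injects a
human-typical torque (right-frontal/left-occipital petalia, a downward
shift and rightward bend of the occiput), runs the full measurement
pipeline and prints measured vs injected values.  Agreement within
~0.1 mm / 0.2 deg shows the pipeline reads back what was put in.
"""

from braintorque import TorqueParams, apply_torque, make_brain, measure_subject

brain = make_brain(resolution=48)
params = TorqueParams(
    petalia_frontal=-0.67, petalia_occipital=-1.58,   # mm, L - R
    shift_frontal=-0.57, shift_occipital=-1.30,       # mm, L - R
    bend_frontal=0.04, bend_occipital=3.63,           # deg, rightward +
    msp_tilt=2.0,                                     # residual registration tilt
)
subject = apply_torque(brain, params)
record = measure_subject(subject)

print(f"{'feature':<20}{'injected':>10}{'measured':>10}")
rows = [
    ("petalia frontal", params.petalia_frontal, record.petalia_frontal),
    ("petalia occipital", params.petalia_occipital, record.petalia_occipital),
    ("shift frontal", params.shift_frontal, record.shift_frontal),
    ("shift occipital", params.shift_occipital, record.shift_occipital),
    ("bending frontal", params.bend_frontal, record.bending_frontal),
    ("bending occipital", params.bend_occipital, record.bending_occipital),
]
for name, injected, measured in rows:
    print(f"{name:<20}{injected:>10.2f}{measured:>10.2f}")
print(f"\nconfiguration: petalia {record.config_petalia.label}, "
      f"shift {record.config_shift.label}, "
      f"bending {record.config_bending.label}")
print("(RF/LO petalia with rightward occipital bending is the "
      "human-typical torque pattern)")
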