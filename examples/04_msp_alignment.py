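"""Mid-sagittal-plane estimation and alignment.

Whole-head linear registration leaves a residual tilt between the
inter-hemispheric fissure and the plane x = 0, which would bias every
left-minus-right measure.  This demo tilts a symmetric brain by 3 degrees,
estimates the MSP from medial-surface vertices of the central brain
portion, aligns, and shows the tilt is removed to below 0.01 degrees.
"""

from braintorque import (TorqueParams, align_to_msp, apply_torque,
                         estimate_msp, make_brain)

brain = make_brain(resolution=48)
tilted = apply_torque(brain, TorqueParams(msp_tilt=3.0))

before = estimate_msp(tilted)
print(f"MSP angle to x-axis before alignment: {before.angle_to_x():7.4f} deg")

aligned = align_to_msp(tilted)
after = estimate_msp(aligned)
print(f"MSP angle to x-axis after alignment:  {after.angle_to_x():7.4f} deg")
print("(below the 0.01 deg tolerance: the fissure now coincides with x = 0)")
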