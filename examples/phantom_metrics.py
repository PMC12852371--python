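"""Generate the default LA phantom and recover all eight metric categories.

The phantom is an ellipsoidal LA cavity (semi-axes 25/20/30 mm, 62.83 mL)
with four radius-6 mm PV sleeves and a frustum LAA (8 -> 3 mm over 25 mm),
voxelized at 0.5 mm.  Every metric has an exact analytic ground truth, so the
printout shows the end-to-end measurement error of the geometry pipeline.
"""

from atriometry import compute_all_metrics, generate_phantom
from atriometry.phantom import PhantomSpec

lm, truth = generate_phantom(PhantomSpec())
report = compute_all_metrics(lm)

rows = [
    ("LA volume [mL]", report.la_volume, truth.la_volume_ml),
    ("LAA volume [mL]", report.laa_volume, truth.laa_volume_ml),
    ("AP diameter [mm]", report.ap_diameter, truth.ap_diameter),
    ("ML diameter [mm]", report.ml_diameter, truth.ml_diameter),
    ("SI diameter [mm]", report.si_diameter, truth.si_diameter),
    ("Left PV ostial diameter [mm]", report.left_pv_diameter, truth.left_pv_diameter),
    ("Right PV ostial diameter [mm]", report.right_pv_diameter, truth.right_pv_diameter),
    ("Left inter-ostial angle [deg]", report.left_pv_angle, truth.left_pv_angle),
    ("Right inter-ostial angle [deg]", report.right_pv_angle, truth.right_pv_angle),
    ("LAA ostial diameter [mm]", report.laa_ostial_diameter, truth.laa_ostial_diameter),
]
print(f"{'metric':34s} {'measured':>9s} {'truth':>9s} {'error':>8s}")
for name, measured, analytic in rows:
    print(f"{name:34s} {measured:9.2f} {analytic:9.2f} {measured - analytic:+8.3f}")
print("QC flags:", report.flags or "none")
# A clean run recovers volumes within ~0.5%, diameters to the voxel, and
# angles within a fraction of a degree; flags list any degraded structure.
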