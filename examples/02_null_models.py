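"""The analytic and Monte-Carlo reference models.

These are the numbers measured network statistics are judged against:
random filament orientations, random 3-way branching angles, the
rigid-rod constraint near a membrane, the Euler buckling force and the
isosceles-triangle reading of tortuosity.
"""

from spinemesh import nulls

print(f"random orientation mean:      {nulls.random_orientation_reference():.2f} deg "
      "(sin-weighted mean = 1 radian)")

ref = nulls.random_branching_angle_reference(n=100_000, seed=0)
print("random sorted branching angles:")
for name, m, s in zip(("smallest", "intermediate", "largest"),
                      ref["means"], ref["sds"]):
    print(f"  {name:13s} {m:6.1f} deg (SD {s:4.1f})")

print("rigid rods (15.4 nm) near a flat membrane:")
for d in (0.0, 2.0, 5.0, 7.7):
    a = nulls.rigid_rod_orientation_analytic(15.4, d)
    print(f"  centre {d:4.1f} nm from the wall -> mean angle {a:5.1f} deg")

print(f"buckling force, 1 um filament: {nulls.buckling_force(0.040, 1.0):.2f} pN")
print(f"tortuosity 1.15 as a bend:     {nulls.tortuosity_base_angle(1.15):.0f} deg base angle")
# A rod squeezed against the membrane must lie parallel to it (90 deg);
# away from the wall the mean relaxes to the random 57.3 deg.
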