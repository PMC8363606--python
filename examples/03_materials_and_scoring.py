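"""Constitutive table, plaque scoring and material assignment.

Shows the five plaque stress-strain classes, how an OCT composition
(lipid / fibrous / calcified fractions) maps to a quarter-step score,
and how a fractional score interpolates between class curves.
"""

from stentsim import materials as M

table = M.default_table()

print("uniaxial Cauchy stress at stretch 1.2 (MPa):")
for name in M.PLAQUE_CLASSES:
    sigma = M.uniaxial_stress(table.hyperelastic[name], 1.2)
    score = table.plaque_scores[name]
    print(f"  {name:>10s} (score {score:+d}): {sigma:8.3f}")
print("  (strictly increasing: stiffer class, larger stress; very stiff is"
      " capped at its 627 MPa yield)")

print("\nplaque scores from OCT composition fractions (lipid, fibrous, calcified):")
for comp in [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0), (0.2, 0.5, 0.3)]:
    print(f"  {comp} -> {M.score_composition(*comp):+.2f}")

lam, sigma_half = M.curve_for_score(0.5, [1.2])
lo = M.uniaxial_stress(table.hyperelastic["neutral"], 1.2)
hi = M.uniaxial_stress(table.hyperelastic["stiff"], 1.2)
print(f"\nscore +0.50 at stretch 1.2: {sigma_half[0]:.3f} MPa "
      f"(midpoint of neutral {lo:.3f} and stiff {hi:.3f})")

c10 = M.fit_neo_hookean([1.05, 1.1, 1.2, 1.3], [M.neo_hookean_stress(0.154, l) for l in (1.05, 1.1, 1.2, 1.3)])
print(f"Neo-Hookean fit to bench silicone samples recovers C10 = {c10:.3f} MPa")
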