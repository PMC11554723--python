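"""Demographic correction grids from the published equations.

Evaluates the published Corsi Span correction equation on the printed
age x education lattice and shows clinical nearest-value lookup.
"""

from corsinorm import CS_EQUATION, CSSL_EQUATION, apply_correction, build_grid, lookup_correction

grid = build_grid(CS_EQUATION)
print("CS correction at age 20, education 5: "
      f"{grid.cell(age=20, education=5):+.2f}")          # -0.10, as printed
print("CS correction at age 85, education 5: "
      f"{grid.cell(age=85, education=5):+.2f}")          # +1.00, as printed

# Clinical lookup snaps to the nearest lattice point (ties toward lower).
print("Nearest-cell lookup for age 22, education 5: "
      f"{lookup_correction(grid, age=22, education=5):+.2f}")

# Precise scoring uses the unrounded equation; supraspan equations also
# adjust for the individual's span.
adjusted = apply_correction(raw=14.0, age=72, education=8, equation=CSSL_EQUATION, span=4)
print(f"CSSL raw 14.0 at age 72, education 8, span 4 -> adjusted {adjusted:.2f}")
# Older, less educated, low-span participants receive positive corrections.
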