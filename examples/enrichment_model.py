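"""Steady-state bud enrichment under free diffusion vs anchoring.

Solves the reaction-diffusion-binding model on the default mother-bud
geometry for the three study scenarios and prints the fraction of mRNA mass
in the bud.  Free diffusion alone cannot concentrate the transcript; the
high-binding (anchored) scenario retains most of it at the production site.
"""

from budmrna.rdmodel import Geometry, GridSpec, scenario_sweep

rows = scenario_sweep(Geometry(), ["free_slow", "free_fast", "anchored"], GridSpec(h=0.5))
print(f"{'scenario':<10} {'bud_fraction':>12} {'bound_fraction':>14} {'total_mass':>11}")
for r in rows:
    print(f"{r.scenario:<10} {r.bud_fraction:>12.3f} {r.bound_fraction:>14.3f} {r.total_mass:>11.1f}")
# bud_fraction: share of steady-state mRNA (free + bound) inside the bud;
# bound_fraction: share of molecules in the immobile bound pool (20 % for the
# default rates, ~97 % when k_on is raised 125-fold).
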