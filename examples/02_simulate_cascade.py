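"""Kinetic simulation of the one-pot reaction.

Runs the calibrated parameter set with every enzyme at 5 mM/min (the
phosphoketolase F6P activity following at the bifunctional 1:0.12
ratio) and the PHB synthase raised to 8 mM/min, on the standard load of
100 mM maltodextrin glucose equivalents.  Substrate consumption stops
when maltodextrin reaches 40% of its initial value — the empirical
limit of alpha-glucan phosphorylase — and the downstream cascade drains
the remaining intermediates.
"""

from phbcascade import (ScenarioSpec, build_network, initial_phb_rate,
                        metrics_from_result, shipped_params, simulate)

net = build_network("full")
params = shipped_params("model1")
vmax = {rid: 5.0 for rid in params.reactions}
vmax.update(FPK=0.6, PhaC=8.0)

result = simulate(net, params.with_vmax(vmax), ScenarioSpec(t_end=240.0))
metrics = metrics_from_result(result)

print(f"substrate consumed   {metrics['consumed_mM']:.1f} mM glucose equivalents")
print(f"stop event at        {metrics['event_time_min']:.1f} min")
print(f"PHB at event         {metrics['phb_at_event_mM']:.1f} mM")
print(f"PHB at 240 min       {metrics['final_titer_mM']:.1f} mM monomer equivalents")
print(f"molar yield          {metrics['molar_yield_percent']}%")
print(f"initial PHB rate     {initial_phb_rate(result):.1f} mM/h")

# Consumption is pinned at 60 mM by the 40% stop event; the final titer
# approaches the theoretical 4/3 ratio (80 mM) as the intermediate pools
# empty, so values just below 80 mM indicate near-complete conversion.
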