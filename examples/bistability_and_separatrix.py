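"""Bistability in Phase II: the initial cell load decides healing vs scarring.

Inside the bistable wedge the saddle's stable manifold (the basin
separatrix) divides the macrophage-fibroblast state plane: starts on one
side relax to the healthy state, starts on the other side develop
fibrosis.  Fibrotic equilibria are further labeled "hot" (macrophage-rich)
or "cold" (fibroblasts persist with few macrophages).
"""

from fibrophase import (
    BASELINE_PARAMS as P,
    Environment,
    ReducedState,
    attractor_of,
    basin_separatrix,
    classify_phase,
    fibrosis_temperature,
    find_steady_states,
)

env = Environment(y=0.1, H=1.33)
print(f"environment y={env.y}, H={env.H} -> Phase {classify_phase(P, env)}")

for eq in find_steady_states(P, env):
    line = f"  {eq.branch:13s} m={eq.state.m:7.4f} f={eq.state.f:6.4f} [{eq.stability_class}]"
    if eq.is_stable:
        line += f"  temperature={fibrosis_temperature(eq, P, env)}"
    print(line)

sep = basin_separatrix(P, env)
print(f"separatrix: {len(sep.curve)} points through saddle (m={sep.saddle.m:.4f}, f={sep.saddle.f:.4f})")

for m0, f0 in [(0.05, 0.05), (0.5, 0.6), (0.3, 0.9)]:
    fate = attractor_of(P, env, ReducedState(m=m0, f=f0))
    print(f"  start m={m0:.2f}, f={f0:.2f} -> {fate}")
print(
    "meaning: moderate macrophage and fibroblast loads scar irreversibly even "
    "though a healthy attractor still exists; only low-load states recover."
)
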