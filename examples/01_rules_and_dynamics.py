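"""Define a small Boolean network and follow a trajectory to its attractor.

The rule dialect is one line per gene ("GENE* = expr"); genes without a
rule are frozen inputs.  All genes update synchronously, so the two-gene
swap below cycles instead of collapsing to a fixed point.
"""

from scboolnet import parse_rules, simulate_to_attractor, synchronous_step

net = parse_rules("""
# p53 toggle with a frozen damage signal
inputs: DAMAGE
TP53* = DAMAGE and not MDM2
MDM2* = TP53
""")

state = net.state([1, 0, 0])  # DAMAGE on, TP53 and MDM2 off
print("genes:", net.symbols)
print("start:", state.packed())
print("one step:", synchronous_step(net, state).packed())

res = simulate_to_attractor(net, state)
print(f"attractor after {res.trajectory.steps_to_cycle} steps: "
      f"period {res.attractor.period} ({res.attractor.kind})")
for s in res.attractor.cycle:
    print("  cycle state:", s.packed())
# With DAMAGE held on, TP53 and MDM2 chase each other around the delayed
# negative feedback loop: a period-4 cycle, never a fixed point.
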