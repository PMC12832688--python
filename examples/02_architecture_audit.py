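"""Assemble the network and audit its parameter and complexity budget.

Prints the per-layer trainable-parameter report of the 224x224x3 build
and the multiply-accumulate comparison between standard and
depthwise-separable convolutions.
"""

from pneunet.model import build_pneunet, complexity_report, param_report

net = build_pneunet()
report = param_report(net)
print(report)
print()
print("multiply-accumulates per spatial position (standard vs separable):")
for name, eq1, eq2 in complexity_report(net):
    note = f"  separable {eq2:,}  ({eq2 / eq1:.1%} of standard)" if eq2 else ""
    print(f"  {name:<20} standard {eq1:>8,}{note}")
print()
print("the audited counts (896, 2,184, 1,280, 4,128, 36,896, 16,512, 16,641,"
      " 129) are the per-layer budget of the architecture; separable blocks"
      " run at ~14% of the cost of the standard convolutions they replace.")
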