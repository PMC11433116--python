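"""Deterministic base case: both treatment arms at both proton fee levels.

Builds the packaged cohort model, runs the proton (PBT) and photon
(3D-CRT) arms over the 60-month horizon, and prints discounted costs,
QALYs and the incremental cost-effectiveness ratio (ICER).  The verdict
compares the ICER with Japan's 7.5M yen/QALY willingness-to-pay threshold
for anticancer therapy.
"""

from markovcua import run_base_case

for fee_level in ("rare", "non_rare"):
    res = run_base_case(fee_level)
    print(f"\n=== {fee_level} cancer fee level ===")
    for out in (res.comparator, res.reference):
        print(f"  {out.strategy:6s} cost {out.total_cost:12,.0f} yen   "
              f"effectiveness {out.total_qaly:.4f} QALY")
    print(f"  incremental cost {res.cea.delta_cost:12,.0f} yen")
    print(f"  incremental effectiveness {res.cea.delta_qaly:.4f} QALY")
    print(f"  ICER {res.cea.icer:,.0f} yen/QALY -> {res.verdict} at "
          f"{res.cea.wtp:,.0f} yen/QALY")

print(
    "\nThe proton arm buys ~0.11 extra QALYs (fewer severe late toxicities)"
    "\nat an extra cost dominated by the radiotherapy fee: cost-effective"
    "\nonly under the lower (non-rare cancer) fee."
)
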