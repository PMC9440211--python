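"""Forward-engineer a promoter with a desired rate at a desired start site.

Simulated annealing over a 60-nt mutable window between fixed flanks,
minimizing the squared log-rate error at the target TSS.
"""

import math

from promotercalc import DesignObjective, load_default_tables, simulate_ground_truth
from promotercalc.design import AnnealSchedule, design_promoter, generate_background

tables = load_default_tables()
params = simulate_ground_truth(seed=0, tables=tables)

flank5 = generate_background(20, seed=11)
flank3 = generate_background(20, seed=12)
target_tss, target_tx = 62, 500.0

objective = DesignObjective(
    targets={target_tss: target_tx},
    five_flank=flank5,
    three_flank=flank3,
    mutable_length=60,
)
result = design_promoter(
    objective, params, tables=tables, schedule=AnnealSchedule(steps=2000), seed=0
)
call = next(c for c in result.profile.forward if c.position == target_tss)

print(f"designed region: {result.sequence[result.mutable_start:result.mutable_end]}")
print(f"target: TX={target_tx:.1f} at TSS {target_tss}; "
      f"achieved TX={call.tx_rate:.2f} (|log error| = "
      f"{abs(math.log(call.tx_rate) - math.log(target_tx)):.3f})")
print(f"annealing cost fell from {result.trace[0]:.2f} to {result.cost:.4f} "
      f"over {len(result.trace) - 1} proposals")
print("cost is the squared log-rate error at the target start site; the")
print("designed 60-mer realizes the requested rate inside its fixed context.")
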