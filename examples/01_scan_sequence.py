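"""Scan a DNA sequence into a transcriptional profile.

Builds a sequence with a strong embedded promoter (consensus -35/-10
hexamers, 17-bp spacer) inside neutral background DNA, scans every
position on both strands, and prints the strongest predicted start sites.
"""

from promotercalc import load_default_tables, scan_profile, simulate_ground_truth
from promotercalc.design import generate_background

tables = load_default_tables()
params = simulate_ground_truth(seed=0, tables=tables)  # canonical-motif demo model

bg = generate_background(160, seed=7)
# drop a consensus promoter into the middle: UP context | TTGACA | 17-bp | TATAAT
promoter = "TTGACA" + bg[10:27] + "TATAAT"
sequence = bg[:60] + promoter + bg[60:130]

profile = scan_profile(sequence, params, tables=tables, sequence_id="demo")
top = sorted(profile.forward + profile.reverse, key=lambda c: -c.tx_rate)[:3]

print(f"scanned {len(sequence)} nt; {len(profile.forward)} forward and "
      f"{len(profile.reverse)} reverse TSS positions evaluated")
for call in top:
    print(f"  {call.strand:7s} TSS@{call.position:3d}  dG_total={call.dg_total:+.2f} RT  "
          f"TX={call.tx_rate:.1f} (vs reference {params.tx_ref:.1f})")
print("each line is one candidate start site: the minimum-energy RNAP/sigma70")
print("binding geometry there and the initiation rate it implies relative to the")
print("reference promoter (lower dG_total means a stronger site).")
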