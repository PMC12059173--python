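"""Nearest-neighbor proximity of imaging phenotypes by TLS status.

Per core, each CD4 TexProg/Tfh cell's distance to its nearest B cell is
computed and summarized by the median; cores are grouped by status. mTLS
cores were simulated with both phenotypes clustered around shared parents,
so their medians should undercut the CSR (nTLS/imTLS) cores.
"""

from pathlib import Path

from tlsarch import io
from tlsarch.proximity import proximity_summary, status_medians

OUT = Path("results/analysis")

if __name__ == "__main__":
    points = io.read_points(OUT / "inputs" / "points.csv")
    pairs = [("CD4_TexProg_Tfh", "B"), ("B", "CD4_TexProg_Tfh")]
    summary = proximity_summary(points, pairs)
    io.write_table(summary, OUT / "proximity.csv")
    med = status_medians(summary)
    io.write_table(med, OUT / "proximity_status_medians.csv")
    print("median nearest-neighbor distance (um) by status and pair:")
    print(med.to_string(index=False))
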