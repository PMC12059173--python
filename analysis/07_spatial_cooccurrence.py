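"""Cell-type co-occurrence on spot-level abundances.

Scores every type pair with (sum_j C_Aj C_Bj / N) x 1000. The spot
simulation shares a latent factor between B and CD4 T abundances, so that
pair should exceed its independence value (product of mean abundances x
1000) while other pairs sit near theirs.
"""

from pathlib import Path

from tlsarch import io
from tlsarch.cooccurrence import cooccurrence_long, cooccurrence_matrix

OUT = Path("results/analysis")

if __name__ == "__main__":
    spots = io.read_spots(OUT / "inputs" / "spots.csv")
    M = cooccurrence_matrix(spots)
    io.write_table(M.rename_axis("cell_type"), OUT / "cooccurrence.csv", index=True)
    io.write_table(cooccurrence_long(M), OUT / "cooccurrence_long.csv")
    print("co-occurrence matrix (x1000):")
    print(M.round(1).to_string())
    means = spots.mean()
    for a, b in (("B", "CD4T"), ("CD8T", "DC")):
        indep = means[a] * means[b] * 1000
        print(f"{a}-{b}: score {M.loc[a, b]:.1f} vs independence {indep:.1f} "
              f"(ratio {M.loc[a, b] / indep:.2f})")
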