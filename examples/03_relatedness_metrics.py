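"""Patristic distances and MPD/MNTD on a worked three-tip tree.

Tree ((A:1,B:1):1,C:2): A and B are sisters two branch-length units apart;
C is four units from each.  The script prints the cophenetic matrix, the
relatedness of a focal invader A to the native pool {B, C}, the native
community diversity of {A, B, C}, and the phylogenetic covariance matrix.
"""

from invaphylo import (
    cophenetic_distances,
    native_diversity,
    phylo_covariance_matrix,
    read_newick,
    relatedness_to_natives,
)

tree = read_newick("((A:1,B:1):1,C:2);", from_string=True)
D = cophenetic_distances(tree)
print("cophenetic distances:")
print(D.to_frame())

pair = relatedness_to_natives("A", ["B", "C"], D)
print(f"\nfocal A vs natives {{B, C}}: MPD = {pair.mpd}  MNTD = {pair.mntd}")
print("(MPD = mean(2, 4) = 3; MNTD = min(2, 4) = 2)")

div = native_diversity(["A", "B", "C"], D)
print(
    f"\nnative community {{A, B, C}}: richness = {div.richness}, "
    f"native MPD = {div.native_mpd:.4f}, native MNTD = {div.native_mntd:.4f}"
)
print("(native MPD = (2+4+4)/3 = 10/3; native MNTD = (2+2+4)/3 = 8/3)")

C = phylo_covariance_matrix(tree)
print("\nphylogenetic covariance (shared root-to-ancestor path):")
print(C)
print("identity: C[i,i] + C[j,j] - 2 C[i,j] equals the distance matrix above")
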