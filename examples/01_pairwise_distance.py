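"""Pairwise alignment-free distance between two protein sequences.

Two sequences sharing the five-residue fragment ACDEF are compared.  The
Local Matching Score sums BLOSUM62 diagonal scores over every residue
covered by a shared fragment on either side; dividing by the combined
diagonal self-scores turns it into a distance in [0, 1] (0 = identical,
1 = no shared fragment).
"""

from fragclust import (
    diagonal_self_score,
    lms_score,
    load_substitution_matrix,
    matched_coverage,
    pairwise_distance,
)

a, b = "ACDEFGH", "MMACDEFYY"
m = load_substitution_matrix("BLOSUM62")

pos_a, pos_b = matched_coverage(a, b)
print(f"sequence a: {a}")
print(f"sequence b: {b}")
print(f"covered positions in a: {sorted(pos_a)}")
print(f"covered positions in b: {sorted(pos_b)}")
print(f"local matching score LMS(a,b): {lms_score(a, b, m)}")
print(f"self-scores S(a)={diagonal_self_score(a, m)}, S(b)={diagonal_self_score(b, m)}")
d = pairwise_distance(a, b, m)
print(f"normalized distance d = 1 - LMS/(S(a)+S(b)) = {d:.4f}")
print("-> ~0.39: the shared ACDEF block covers about 60% of the total")
print("   self-similarity weight; unrelated sequences would score 1.0.")
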