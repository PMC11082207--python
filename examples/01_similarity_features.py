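"""Compute the two similarity features behind the model for a compound pair.

Two celecoxib-like sulfonamides are featurized (3D conformers -> ES5D shape
vectors; 2D structure -> 1024-bit path fingerprint) and compared: the
3D-Score is the best conformer-pair Manhattan shape similarity, the
2D-Score the fingerprint Tanimoto coefficient.  Close analogs score high on
both; an unrelated molecule scores low.
"""

from revscreen import best_pair_similarity, featurize, tanimoto

compounds = {
    "analog_a": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "analog_b": "CCc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "unrelated": "CN1CCC(OC(=O)C(c2ccccc2)c2ccccc2)CC1",
}

descriptors = featurize(compounds, n_conformers=5, seed=1)

for other in ("analog_b", "unrelated"):
    s3 = best_pair_similarity(descriptors["analog_a"].es5d,
                              descriptors[other].es5d)
    s2 = tanimoto(descriptors["analog_a"].fingerprint,
                  descriptors[other].fingerprint)
    print(f"analog_a vs {other}: 3D-Score {s3:.3f}  2D-Score {s2:.3f}")

print("\n3D-Score in (0,1] decreases with conformer shape distance;"
      "\n2D-Score in [0,1] is the shared fraction of linear-path bits."
      "\nThe analog pair should dominate the unrelated pair on both scores.")
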