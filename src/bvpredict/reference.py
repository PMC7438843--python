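"""Published reference values used as worked examples.

``meatal_importance_ranks`` is the published per-classifier variable
importance ranking of the top 20 meatal variables (19 taxa plus circumcision
status) for predicting incident BV, together with the published ensemble
voting rank. The per-classifier columns feed :func:`~bvpredict.importance
.average_ranks` as a worked example; the voting column is what that
aggregation should reproduce, including its three tied mean-rank pairs.
"""

from __future__ import annotations

import pandas as pd

_MEATAL_RANK_ROWS = [
    # (variable, knn, rf, svm, published voting rank)
    ("Parvimonas", 3, 4, 4, 1),
    ("Lactobacillus iners", 6, 1, 13, 2),
    ("Fastidiosipila", 5, 12, 11, 3),
    ("Negativicoccus", 1, 2, 27, 4),
    ("Lactobacillus crispatus", 10, 20, 7, 5),
    ("Dialister", 16, 5, 19, 6),
    ("Sneathia sanguinegens", 11, 7, 22, 7),
    ("Gardnerella vaginalis", 8, 8, 26, 8),
    ("Prevotella corporis", 18, 15, 9, 9),
    ("Corynebacterium", 17, 16, 16, 10),
    ("Sneathia amnii", 4, 9, 42, 11),
    ("Chryseobacterium", 33, 10, 14, 12),
    ("Acinetobacter", 7, 6, 45, 13),
    ("Escherichia shigella", 15, 45, 2, 14),
    ("Gemella", 40, 3, 20, 15),
    ("Prevotella timonensis", 30, 28, 5, 16),
    ("Circumcised (vs. uncircumcised)", 9, 27, 32, 17),
    ("Peptostreptococcus", 2, 18, 49, 18),
    ("Ezakiella", 21, 11, 43, 19),
    ("Alloprevotella", 19, 23, 36, 20),
]

# Published class counts used in worked examples of the SMOTE arithmetic:
# (minority, majority) sizes of the two training sets before rebalancing.
MEATAL_CLASS_COUNTS = (52, 116)
GLANS_CLASS_COUNTS = (24, 54)


def meatal_importance_ranks() -> pd.DataFrame:
    """Published top-20 meatal importance ranks (KNN, RF, SVM, voting)."""
    frame = pd.DataFrame(
        _MEATAL_RANK_ROWS,
        columns=["feature", "rank_knn", "rank_rf", "rank_svm", "published_voting_rank"],
    ).set_index("feature")
    return frame
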