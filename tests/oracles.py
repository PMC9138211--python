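"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity from first principles (subset
enumeration, explicit sum-of-squares loops) and never call the code paths
they validate.
"""

import itertools
import math


def brute_force_dominant(panel, wheal_margin=5.0, log_margin=0.5, floor=0.01):
    """Dominant set by exhaustive subset enumeration.

    ``panel`` maps allergen source -> (wheal_mm, specific_ige) for positive
    sensitizations.  Returns the frozenset of sources in the smallest subset
    whose every member exceeds every non-member by both margins; with no
    separating subset, all sources are co-dominant.
    """
    items = [(s, w, max(g, floor)) for s, (w, g) in panel.items()]
    for k in range(1, len(items)):
        winners = []
        for subset in itertools.combinations(items, k):
            chosen = set(s for s, _, _ in subset)
            rest = [it for it in items if it[0] not in chosen]
            if all(
                m[1] - r[1] >= wheal_margin
                and math.log10(m[2]) - math.log10(r[2]) >= log_margin
                for m in subset
                for r in rest
            ):
                winners.append(frozenset(chosen))
        if winners:
            assert len(winners) == 1, "separating subsets of one size must be unique"
            return winners[0]
    return frozenset(s for s, _, _ in items)


def rm_anova_f_by_hand(matrix):
    """Within-subject one-way F via explicit sum-of-squares loops."""
    n = len(matrix)
    k = len(matrix[0])
    grand = sum(sum(row) for row in matrix) / (n * k)
    col_means = [sum(row[j] for row in matrix) / n for j in range(k)]
    row_means = [sum(row) / k for row in matrix]
    ss_time = n * sum((m - grand) ** 2 for m in col_means)
    ss_subj = k * sum((m - grand) ** 2 for m in row_means)
    ss_total = sum((x - grand) ** 2 for row in matrix for x in row)
    ss_err = ss_total - ss_time - ss_subj
    return (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


def oneway_f_by_hand(groups):
    """Between-group one-way F via explicit sum-of-squares loops."""
    all_values = [x for g in groups for x in g]
    n, k = len(all_values), len(groups)
    grand = sum(all_values) / n
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    return (ss_between / (k - 1)) / (ss_within / (n - k))
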