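import pytest

from cotscan.core import DEFAULT_SCHEME
from cotscan.motif import ccm_pattern_family


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def family(scheme):
    return ccm_pattern_family(scheme)


def brute_force_scan(sequence: str, scheme=DEFAULT_SCHEME):
    """Independent motif matcher: tries every geometry at every offset
    straight from the motif definition, then collapses parses per first-
    patch start (shortest separator, longest second patch, flanks by
    direct adjacency). Used as the oracle for scan_sequence."""
    seq = sequence.upper()
    n = len(seq)
    small, bulky, flank = scheme.small, scheme.bulky, scheme.flank
    combos_by_p1 = {}
    for p1 in range(n - 4):  # patch1 needs 2 + sep >= 2 + patch2 >= 1
        if not all(r in small for r in seq[p1 : p1 + 2]):
            continue
        for sep in (2, 3):
            for p2l in (1, 2):
                sep_end = p1 + 2 + sep
                p2_end = sep_end + p2l
                if p2_end > n:
                    continue
                if not all(r in bulky for r in seq[p1 + 2 : sep_end]):
                    continue
                if not all(r in small for r in seq[sep_end:p2_end]):
                    continue
                left = p1 - 1 >= 0 and seq[p1 - 1] in flank
                right = p2_end < n and seq[p2_end] in flank
                if not (left or right):
                    continue
                combos_by_p1.setdefault(p1, set()).add((sep, p2l))
    matches = []
    for p1 in sorted(combos_by_p1):
        combos = combos_by_p1[p1]
        sep = min(s for s, _ in combos)
        p2l = max(p for s, p in combos if s == sep)
        sep_end = p1 + 2 + sep
        p2_end = sep_end + p2l
        left = p1 - 1 >= 0 and seq[p1 - 1] in flank
        right = p2_end < n and seq[p2_end] in flank
        matches.append(
            {
                "patch1": (p1 + 1, p1 + 2),
                "separator": (p1 + 3, sep_end),
                "patch2": (sep_end + 1, p2_end),
                "left_flank": p1 if left else None,
                "right_flank": p2_end + 1 if right else None,
            }
        )
    return matches


@pytest.fixture(scope="session")
def oracle_scan():
    return brute_force_scan
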