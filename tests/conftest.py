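import pytest

from coexmine import ComparisonRecord, ProbeGeneMap, ProbeMeasure

# state codes for hand-built pattern stores:
#   '.' absent, 'n' measured but not significant,
#   'p' present (significant, |lfc| below threshold),
#   'u' modulated up, 'd' modulated down
STATE_MEASURES = {
    "n": (0.0, 0.5, 0.5),
    "p": (0.3, 0.005, 0.02),
    "u": (1.5, 0.001, 0.01),
    "d": (-1.5, 0.001, 0.01),
}


def make_pattern_store(patterns, oriented=True):
    """Build (records, probe_map) from per-gene state strings.

    ``patterns`` maps gene symbol -> a string with one state code per
    comparison; every gene gets a single probe ``pr_<gene>``. ``oriented``
    may be a bool or a per-comparison sequence.
    """
    genes = list(patterns)
    n = len(next(iter(patterns.values())))
    assert all(len(s) == n for s in patterns.values())
    flags = [oriented] * n if isinstance(oriented, bool) else list(oriented)
    records = []
    for ci in range(n):
        measures = []
        for g in genes:
            code = patterns[g][ci]
            if code == ".":
                continue
            lfc, p, adj = STATE_MEASURES[code]
            measures.append(ProbeMeasure(f"pr_{g}", lfc, p, adj))
        if measures:
            records.append(
                ComparisonRecord(f"c{ci:02d}", "DS0", bool(flags[ci]), tuple(measures))
            )
    probe_map = ProbeGeneMap({f"pr_{g}": g for g in genes})
    return records, probe_map


@pytest.fixture
def pattern_store():
    return make_pattern_store
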