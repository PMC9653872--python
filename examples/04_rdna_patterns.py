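"""5S/45S rDNA distribution patterns across eleven cherry relatives.

Loads the shipped per-species site table, groups species by canonical
(ploidy-independent) signature, and predicts metaphase signal-pair counts.
"""

from oligofish.karyotype import (
    expected_signal_pairs,
    load_rdna_patterns,
    pattern_signature,
)

patterns = load_rdna_patterns()
groups: dict[str, list[str]] = {}
for name, p in patterns.items():
    groups.setdefault(pattern_signature(p), []).append(name)

print(f"{len(patterns)} species fall into {len(groups)} distribution types:\n")
for i, (sig, species) in enumerate(groups.items(), start=1):
    print(f"type {i}: {', '.join(species)}")
    print(f"   sites: {sig}")

pp = patterns["P. pseudocerasus"]
print(
    f"\ntetraploid P. pseudocerasus: "
    f"{expected_signal_pairs(pp, '45S')} pairs of 45S signals and "
    f"{expected_signal_pairs(pp, '5S')} pairs of 5S signals expected"
)
print("  (sites per basic genome x ploidy/2 — what a metaphase spread shows)")
av = patterns["P. avium"]
print(
    f"diploid P. avium: {expected_signal_pairs(av, '45S')} pairs 45S, "
    f"{expected_signal_pairs(av, '5S')} pair 5S"
)
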