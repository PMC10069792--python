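"""Default inter-residue pair catalog for the distance feature set.

The structural feature vector holds 62 minimum inter-residue distances in
five categories: trigger-loop internal pairs (TL-TL), trigger-loop to
bridge-helix pairs (TL-BH), bridge-helix internal pairs (BH-BH),
trigger-loop residues against the GTP substrate (TL-GTP), and GTP against
other active-site partners (Mg2+, terminal RNA, templating DNA).

The pairs named explicitly in the literature (K830-V1094, D826-V1094,
G819-G1088, H1085-GTP, L1081-GTP, the GTP Pa - RNA O3' catalytic
distance, the GTP-Mg2+ distance, the GTP/DNA base-pair and sugar-carbon
distances, T1083-K1093, N1082-K1093, T1080-V1094) are included; the
remainder are systematic near-neighbour pairs within and between the two
elements.  Real-data runs may replace the catalog with the study's own
62-pair list via :func:`polphen.io.read_distance_table`.
"""

from __future__ import annotations

# Trigger-loop residues by author (Rpb1) numbering, matching the default
# WT sequence in polphen.synth.
TL_RESIDUES = {
    1076: "A", 1077: "T", 1078: "Q", 1079: "M", 1080: "T", 1081: "L",
    1082: "N", 1083: "T", 1084: "F", 1085: "H", 1086: "F", 1087: "A",
    1088: "G", 1089: "V", 1090: "E", 1091: "S", 1092: "K", 1093: "K",
    1094: "V", 1095: "A", 1096: "A", 1097: "G", 1098: "V", 1099: "P",
    1100: "R", 1101: "L", 1102: "S", 1103: "E", 1104: "I", 1105: "L",
    1106: "N",
}

# Bridge-helix residues referenced by the distance catalog.
BH_RESIDUES = {819: "G", 826: "D", 830: "K", 834: "T", 836: "Y", 837: "I", 841: "L"}


def _tl(pos: int) -> str:
    return f"{TL_RESIDUES[pos]}{pos}"


def _bh(pos: int) -> str:
    return f"{BH_RESIDUES[pos]}{pos}"


def default_pair_catalog() -> list[tuple[str, str]]:
    """The built-in 62-entry (name, category) catalog."""
    pairs: list[tuple[str, str]] = []

    # GTP against Mg2+, terminal RNA and the templating DNA base. (4)
    pairs += [
        ("GTP_Pa-RNA_O3'", "GTP-other"),
        ("GTP-Mg", "GTP-other"),
        ("GTP_C1'-DNA_C1'", "GTP-other"),
        ("GTP_H1-DNA_N3", "GTP-other"),
    ]

    # TL residues close to the substrate. (12)
    for pos in (1078, 1079, 1080, 1081, 1082, 1083, 1084, 1085, 1086, 1087, 1088, 1089):
        pairs.append((f"{_tl(pos)}-GTP", "TL-GTP"))

    # TL-BH contacts, anchored by the named V1094/G1088 partners. (14)
    tl_bh = [
        (830, 1094), (826, 1094), (819, 1088), (830, 1088), (826, 1088),
        (819, 1094), (841, 1079), (837, 1076), (841, 1101), (837, 1097),
        (834, 1089), (836, 1086), (830, 1080), (826, 1081),
    ]
    pairs += [(f"{_bh(b)}-{_tl(t)}", "TL-BH") for b, t in tl_bh]

    # BH internal pairs. (8)
    bh_bh = [(819, 826), (826, 830), (830, 834), (834, 836), (836, 837),
             (837, 841), (819, 830), (826, 834)]
    pairs += [(f"{_bh(a)}-{_bh(b)}", "BH-BH") for a, b in bh_bh]

    # TL internal pairs: the named trio plus i/i+3 neighbours. (24)
    tl_tl = [(1083, 1093), (1082, 1093), (1080, 1094)]
    tl_tl += [(p, p + 3) for p in range(1076, 1096)]   # 20 pairs
    tl_tl += [(1097, 1100)]
    pairs += [(f"{_tl(a)}-{_tl(b)}", "TL-TL") for a, b in tl_tl]

    assert len(pairs) == 62
    return pairs


DEFAULT_PAIR_NAMES: list[str] = [name for name, _ in default_pair_catalog()]
DEFAULT_PAIR_CATEGORIES: dict[str, str] = dict(default_pair_catalog())
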