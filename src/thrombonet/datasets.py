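"""Published reference tables bundled with the package.

:data:`THROMBOSIS_HUB_TABLE` is the published hub table of the human
thrombosis network (the 27 proteins with degree >= 10 and their
centralities), useful as a realistic worked example for hub extraction
and the multifunctional-vs-nonmultifunctional group comparison.  The
full 149-node network behind it was never deposited, so these 27 rows
are the only real-data anchor available.
"""

from __future__ import annotations

from .centrality import CentralityRecord

_FUNC = {
    "Platelet signaling": frozenset({"platelet"}),
    "Coagulation": frozenset({"coagulation"}),
    "Clot dissolution": frozenset({"dissolution"}),
    "Multifunction-pc": frozenset({"platelet", "coagulation"}),
    "Multifunction-cd": frozenset({"coagulation", "dissolution"}),
}

# rank, node, degree, betweenness, closeness, functions
_ROWS = [
    ("Talin-RIAM complex", 25, 689, 6.2, "Platelet signaling"),
    ("GP IIb/IIIa", 23, 215, 6.2, "Platelet signaling"),
    ("Thrombin", 19, 3089, 2.7, "Multifunction-pc"),
    ("GPIb-IX-V", 18, 2818, 2.9, "Multifunction-pc"),
    ("p-Y419-Src", 18, 2866, 4.8, "Platelet signaling"),
    ("Syk", 16, 686, 4.7, "Platelet signaling"),
    ("Plasmin", 15, 294, 1.5, "Clot dissolution"),
    ("CSK", 14, 151, 6.3, "Platelet signaling"),
    ("vWF", 13, 542, 3.4, "Multifunction-pc"),
    ("CLFM", 13, 992, 1.7, "Multifunction-cd"),
    ("Fyn", 12, 133, 5.6, "Platelet signaling"),
    ("GPVI-FcR", 12, 133, 5.6, "Platelet signaling"),
    ("Lyn", 12, 133, 5.6, "Platelet signaling"),
    ("p-Y348-Syk", 12, 288, 6.4, "Platelet signaling"),
    ("Factor Xa", 12, 1032, 3.5, "Coagulation"),
    ("Collagen", 11, 9, 6.4, "Platelet signaling"),
    ("uPAR", 11, 145, 1.5, "Clot dissolution"),
    ("Src", 10, 396, 5.4, "Platelet signaling"),
    ("PDK1", 10, 21, 1.0, "Platelet signaling"),
    ("AKT", 10, 21, 1.0, "Platelet signaling"),
    ("PAI-1", 10, 177, 1.7, "Clot dissolution"),
    ("Crk", 10, 502, 5.5, "Platelet signaling"),
    ("p-Y397, 407, 576, 577, 861, 925-FADK1", 10, 414, 6.4, "Platelet signaling"),
    ("TF", 10, 213, 4.4, "Coagulation"),
    ("Thrombin-activated PAR", 10, 803, 1.8, "Platelet signaling"),
    ("G-protein Gq", 10, 338, 1.5, "Platelet signaling"),
    ("uPA (two-chain)", 10, 53, 1.6, "Clot dissolution"),
]


def thrombosis_hub_table(hub_threshold: int = 10) -> list[CentralityRecord]:
    """The 27 published thrombosis-network hubs as centrality records."""
    return [
        CentralityRecord(
            node=node,
            degree=deg,
            betweenness=float(bet),
            closeness=float(clo),
            functions=_FUNC[func],
            is_multifunctional=len(_FUNC[func]) >= 2,
            is_hub=deg >= hub_threshold,
        )
        for node, deg, bet, clo, func in _ROWS
    ]


THROMBOSIS_HUB_TABLE = thrombosis_hub_table()
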