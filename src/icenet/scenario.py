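"""The default synthetic study: one cohort-shaped configuration.

Defines the planted ground truth used by the numbered analysis scripts and
the acceptance runs: a 109-sample cohort, a miRNA-target map with planted
shared-regulator structure, and an inflammatory ceRNA network containing

* a prognostic clique module of 6 mRNAs + 1 lncRNA carrying nonzero Cox
  coefficients,
* two decoy clique modules with no survival effect,
* three hub stars (one anchored on a lncRNA) that make the degree
  distribution heavy-tailed, and
* disconnected decoy pairs that fall out of the inflammatory subnetwork.

Bridging pairs tie modules and hubs into one connected component.  Each
module and each star is its own latent expression factor; molecules sitting
in two factor groups act as bridges (their pairwise correlation with pure
group members is c/sqrt(2) ~ 0.64 at the default c=0.9, still above the
0.5 acceptance threshold), so decoy modules stay statistically independent
of the prognostic factor while the network remains connected.
"""

from __future__ import annotations

from itertools import combinations

from .synthetic import SyntheticConfig

PROGNOSTIC_MODULE = ["G0000", "G0001", "G0002", "G0003", "G0004", "G0005", "L0000"]
DECOY_MODULE_1 = ["G0010", "G0011", "G0012", "G0013", "G0014", "L0001"]
DECOY_MODULE_2 = ["G0020", "G0021", "G0022", "G0023", "G0024"]

HUB_STARS = {
    "G0030": [f"G{i:04d}" for i in range(40, 48)],
    "G0031": [f"G{i:04d}" for i in range(50, 56)],
    "L0002": [f"G{i:04d}" for i in range(60, 65)],
}

# planted pairs whose endpoints live in different factor groups; the shared
# endpoint of each bridge belongs to both groups.  Every connection is
# doubled so that one bridge pair slipping under the correlation threshold
# by sampling noise cannot sever the subnetwork.
BRIDGES = [
    ("G0000", "G0030"),  # prognostic module <-> star 1
    ("G0001", "G0030"),
    ("G0010", "G0030"),  # decoy module 1    <-> star 1
    ("G0011", "G0030"),
    ("G0020", "G0031"),  # decoy module 2    <-> star 2
    ("G0021", "G0031"),
    ("G0032", "G0030"),  # dedicated bridge nodes between stars 1 and 2
    ("G0032", "G0031"),
    ("G0033", "G0030"),
    ("G0033", "G0031"),
    ("G0060", "G0031"),  # star 3 leaves     <-> star 2
    ("G0061", "G0031"),
]

# mixed signs; the bridge members G0000/G0001 cancel so the star factor
# they also load on carries no net hazard, while the pure module members
# sum to 1.5 and give the module factor a strong effect
MODULE_COEFFICIENTS = {
    "G0000": 0.25,
    "G0001": -0.25,
    "G0002": 0.5,
    "G0003": 0.5,
    "G0004": -0.5,
    "G0005": 0.5,
    "L0000": 0.5,
}

INFLAMMATORY_GENES = [
    "G0000", "G0001",           # inside the prognostic module
    "G0010", "G0020",           # inside the decoy modules
    "G0030", "G0031",           # hub centers
    "G0040", "G0050", "G0060",  # hub leaves
    "G0070", "G0080",           # scattered, degree 0 in the true network
]

N_SHARED_MIRNA = 4

DISCONNECTED_PAIRS = [
    (f"G{i:04d}", f"G{i + 1:04d}") for i in range(100, 120, 2)
]


def planted_pairs() -> list[tuple[str, str, int]]:
    pairs: list[tuple[str, str, int]] = []
    for module in (PROGNOSTIC_MODULE, DECOY_MODULE_1, DECOY_MODULE_2):
        pairs.extend((a, b, N_SHARED_MIRNA) for a, b in combinations(module, 2))
    for hub, leaves in HUB_STARS.items():
        pairs.extend((hub, leaf, N_SHARED_MIRNA) for leaf in leaves)
    pairs.extend((a, b, N_SHARED_MIRNA) for a, b in BRIDGES)
    # decoy pairs: present in the full ceRNA network, absent from the
    # inflammatory subnetwork (no inflammatory gene nearby)
    pairs.extend((a, b, N_SHARED_MIRNA) for a, b in DISCONNECTED_PAIRS)
    return pairs


def factor_groups() -> list[list[str]]:
    groups = [
        list(PROGNOSTIC_MODULE),
        list(DECOY_MODULE_1),
        list(DECOY_MODULE_2),
    ]
    star1 = (["G0030"] + HUB_STARS["G0030"]
             + ["G0000", "G0001", "G0010", "G0011", "G0032", "G0033"])
    star2 = (["G0031"] + HUB_STARS["G0031"]
             + ["G0020", "G0021", "G0032", "G0033", "G0060", "G0061"])
    star3 = ["L0002"] + HUB_STARS["L0002"]
    groups += [star1, star2, star3]
    groups += [[a, b] for a, b in DISCONNECTED_PAIRS]
    return groups


def study_config(seed: int = 0) -> SyntheticConfig:
    """The cohort-scale configuration (109 samples, defaults elsewhere)."""
    return SyntheticConfig(
        planted_pairs=planted_pairs(),
        planted_module=dict(MODULE_COEFFICIENTS),
        inflammatory_genes=list(INFLAMMATORY_GENES),
        factor_groups=factor_groups(),
        seed=int(seed),
    )
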