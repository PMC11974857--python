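"""Reference flagellar-gene-cluster and plasmid-replicase protein sets.

Three FGC types occur in *Rhodobacterales*: the archetypal chromosomal
fla1 (P. inhibens DSM 17395, CP002976.1: PGA1_c35560..PGA1_c35910), the
plasmid-prone fla2 (M. algicola DG898, CP010860.1: MALG_04521..04566)
and the rare fla3 (C. sphaeroides 2.4.1, CP000143.2: RSP_0032..0083).

The sequences shipped here are SYNTHETIC stand-ins generated from a
fixed seed: they carry the real role labels (the 36 fla1 roles including
the conserved proteins CP1-4 and the four cross-type congruence markers
FlhA, FliF, FlgH, FlgI) but not the real residues, so the package is
testable without downloads. Swapping in real reference proteins is a
documented user step (same table layout), not a test dependency.

The same objects serve as ancestral states for the synthetic genome
generator, which is what makes planted clusters detectable by
:mod:`rhodoflag.fgc_typing`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io_formats import AMINO_ACIDS

#: Master seed for the synthetic reference sequences (fixed; part of the fixture).
REFERENCE_SEED = 17395

FLA_TYPES = ("fla1", "fla2", "fla3")

#: The four conserved proteins used for FGC phylogenies across all types.
CONGRUENCE_ROLES = ("flhA", "fliF", "flgH", "flgI")

#: fla1 role inventory: upstream genes 01-29 (motB..fliI) and the more
#: rearrangement-prone downstream genes 30-36 (flbT..flgD, with CP1),
#: including the four Rhodobacterales-specific conserved proteins CP1-4.
FLA1_ROLES = (
    "motB", "flgE", "flgK", "flgL", "flgI", "fliP", "fliN", "fliH", "fliF",
    "fliL", "CP2", "CP3", "motA", "CP4", "sltF", "flhA", "fliR", "flhB",
    "orf19", "flgH", "flgA", "flgG", "flgF", "fliQ", "fliE", "flgC", "flgB",
    "flgJ", "fliI", "flbT", "flaF", "fliC", "flgN", "fliK", "flgD", "CP1",
)

#: fla2 (46 members) and fla3 (52 members) inventories: the four
#: congruence markers plus generic structural roles.
FLA2_ROLES = CONGRUENCE_ROLES + tuple(f"f2orf{i:02d}" for i in range(1, 43))
FLA3_ROLES = CONGRUENCE_ROLES + tuple(f"f3orf{i:02d}" for i in range(1, 49))

SOURCE_LOCI = {
    "fla1": "CP002976.1: PGA1_c35560 to PGA1_c35910",
    "fla2": "CP010860.1: MALG_04521 to MALG_04566",
    "fla3": "CP000143.2: RSP_0032 to RSP_0083",
}

REPLICASE_CLASSES = ("DnaA-like", "RepA", "RepB", "RepABC")


@dataclass(frozen=True)
class RefMember:
    ref_gene_id: str  # "<fla_type>|<role>"
    role: str
    sequence: str


@dataclass(frozen=True)
class ReferenceSet:
    fla_type: str
    members: tuple[RefMember, ...]
    source: str

    def roles(self) -> list[str]:
        return [m.role for m in self.members]

    def sequences(self) -> dict[str, str]:
        return {m.role: m.sequence for m in self.members}


@dataclass(frozen=True)
class ReplicaseRef:
    ref_id: str  # "<class>|<subtype>"
    class_name: str
    subtype: str
    sequence: str


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


@lru_cache(maxsize=1)
def flagellar_references() -> tuple[ReferenceSet, ...]:
    """The three FGC reference sets (deterministic synthetic fixture).

    Member lengths are drawn uniformly in 80..160 aa; the three types are
    mutually unrelated random sequences (deep divergence), so a gene can
    only match the type it descends from.
    """
    out = []
    for t, roles in (("fla1", FLA1_ROLES), ("fla2", FLA2_ROLES), ("fla3", FLA3_ROLES)):
        rng = np.random.default_rng([REFERENCE_SEED, FLA_TYPES.index(t)])
        members = []
        for role in roles:
            # the export/ring proteins used as congruence markers are large
            # (FlhA ~700 aa, FliF ~560 aa); other cluster members are smaller
            length = (
                int(rng.integers(280, 401))
                if role in CONGRUENCE_ROLES
                else int(rng.integers(80, 161))
            )
            members.append(
                RefMember(
                    ref_gene_id=f"{t}|{role}",
                    role=role,
                    sequence=_random_protein(rng, length),
                )
            )
        out.append(ReferenceSet(fla_type=t, members=tuple(members), source=SOURCE_LOCI[t]))
    return tuple(out)


@lru_cache(maxsize=1)
def replicase_references() -> tuple[ReplicaseRef, ...]:
    """Plasmid replication-initiator references: 4 classes x 2 subtypes.

    Classes are mutually unrelated; subtypes within a class differ by
    ~30% of positions (distinct compatibility groups, common class).
    """
    out = []
    for ci, cls in enumerate(REPLICASE_CLASSES):
        rng = np.random.default_rng([REFERENCE_SEED, 100 + ci])
        base = np.array(list(_random_protein(rng, 120)))
        for si in (1, 2):
            seq = base.copy()
            flip = rng.random(len(seq)) < 0.30
            repl = np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=len(seq))]
            seq[flip] = repl[flip]
            out.append(
                ReplicaseRef(
                    ref_id=f"{cls}|{si}",
                    class_name=cls,
                    subtype=str(si),
                    sequence="".join(seq),
                )
            )
    return tuple(out)


def reference_by_type(fla_type: str) -> ReferenceSet:
    for ref in flagellar_references():
        if ref.fla_type == fla_type:
            return ref
    raise KeyError(fla_type)
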