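"""Template-based assembly of representative SMILES strings.

One representative positional isomer is emitted per composition: fatty-acid
double bonds are written *cis* and anchored near the methyl end (the
oleic/linoleic/linolenic pattern: Delta n-9, n-6, n-3), sphingoid double
bonds are written *trans* starting at Delta 4 with methylene-interrupted
spacing.  Strings are plain concatenations of block templates and are not
canonicalized; stereocentres are left unspecified.
"""

from __future__ import annotations

from typing import Dict, List

from .nomenclature import AcylChain, LipidSpecies, SphingoidBase

__all__ = ["assemble_smiles"]


class SmilesAssemblyError(ValueError):
    """Raised when no valid representative structure fits the composition."""


_CIS = "\\"
_TRANS = "/"


def _emit_chain(
    start: int,
    end: int,
    db_starts: List[int],
    substituents: Dict[int, str],
    geometry: str,
) -> str:
    """Emit carbons ``start..end`` (1-indexed along the full chain) with
    double bonds beginning at the listed positions."""
    db_carbons = set()
    for p in db_starts:
        db_carbons.update((p, p + 1))
    clash = db_carbons & set(substituents)
    if clash:
        raise SmilesAssemblyError(
            f"double bond placed on substituted carbon(s) {sorted(clash)}"
        )
    out = []
    i = start
    starts = set(db_starts)
    while i <= end:
        if i in starts:
            if i + 1 > end:
                raise SmilesAssemblyError(f"double bond at C{i} exceeds chain end {end}")
            out.append(f"/C=C{geometry}")
            i += 2
        else:
            out.append("C" + substituents.get(i, ""))
            i += 1
    return "".join(out)


def _double_bond_positions(
    n: int, count: int, anchor: int, min_pos: int, max_last: int
) -> List[int]:
    """Positions of ``count`` methylene-interrupted double bonds.

    ``anchor`` is the preferred first position (e.g. ``n - 9`` for fatty
    acids); the whole series is shifted up if it would collide with a
    substituted carbon, and an error is raised if it cannot fit.
    """
    if count == 0:
        return []
    positions = [anchor + 3 * k for k in range(count)]
    if positions[0] < min_pos:
        shift = min_pos - positions[0]
        positions = [p + shift for p in positions]
    if positions[-1] + 1 > max_last:
        raise SmilesAssemblyError(
            f"{count} double bonds do not fit on a {n}-carbon chain"
        )
    return positions


def _fa_tail(chain: AcylChain) -> str:
    """The acyl chain after the amide carbonyl (positions 2..n)."""
    n = chain.carbons
    subs: Dict[int, str] = {}
    min_db = 2
    max_last = n
    if chain.hydroxy_type == "A":
        subs[2] = "(O)"
        min_db = 3
    elif chain.hydroxy_type == "B":
        subs[3] = "(O)"
        min_db = 4
    elif chain.hydroxy_type == "EO":
        ester = chain.ester_chain
        subs[n] = "OC(=O)" + _fa_tail(AcylChain(ester.carbons, ester.double_bonds, "N"))
        max_last = n - 1
    positions = _double_bond_positions(n, chain.double_bonds, n - 9, min_db, max_last)
    if chain.hydroxy_type == "EO":
        # the omega carbon carries the ester; emit it as chain end with a branch
        body = _emit_chain(2, n - 1, positions, {k: v for k, v in subs.items() if k < n}, _CIS)
        return body + "C" + subs[n]
    return _emit_chain(2, n, positions, subs, _CIS)


def _sphingoid_tail(base: SphingoidBase) -> str:
    """The sphingoid chain after the last headgroup-bearing carbon."""
    if base.kind == "P":
        start, anchor, min_db = 5, 6, 5
    else:
        start, anchor, min_db = 4, 4, 4
    positions = _double_bond_positions(
        base.carbons, base.double_bonds, anchor, min_db, base.carbons
    )
    return _emit_chain(start, base.carbons, positions, {}, _TRANS)


def assemble_smiles(species: LipidSpecies) -> str:
    """A representative (non-canonical, non-stereo) SMILES for a species.

    The emitted string's elemental composition equals
    :func:`sphingolib.nomenclature.species_formula`.
    """
    fa_branch = "NC(=O)" + _fa_tail(species.chain)
    if species.base.kind == "P":
        core = f"CC({fa_branch})C(O)C(O)" + _sphingoid_tail(species.base)
    else:
        core = f"CC({fa_branch})C(O)" + _sphingoid_tail(species.base)
    head = species.head
    if head == "Cer":
        return "O" + core
    if head == "HexCer":
        return "OCC1OC(O" + core + ")C(O)C(O)C1O"
    if head == "SM":
        return "C[N+](C)(C)CCOP(=O)([O-])O" + core
    raise SmilesAssemblyError(f"no SMILES template for head group {head!r}")
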