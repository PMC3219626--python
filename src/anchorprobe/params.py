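"""United-atom parameter set: charges, Lennard-Jones terms, radii, solvation.

The table is a versioned plain-text file shipped with the package
(``data/params_v1.tsv``). Each row parameterizes one heavy atom of one
standard residue: partial charge (elementary charges), LJ well depth
(kcal/mol) and size sigma (A), van der Waals radius (A), atomic solvation
parameter (cal/(mol*A^2), Eisenberg--McLachlan-style class values), and a
polarity flag. Hydrogens are implicit: aliphatic carbons are united atoms,
polar-hydrogen charge is folded into the heavy atom.

An alternative table may be supplied through :class:`ParameterSet`
(``ParameterSet.from_file``); every run logs the table path and checksum.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["AtomParams", "ParameterSet", "default_parameter_set"]

#: |charge| above which a non-N/O/S atom is still considered polar
POLARITY_CHARGE_THRESHOLD = 0.30

#: Coulomb conversion constant, kcal*A/(mol*e^2)
COULOMB_KCAL = 332.0636

#: atoms that may legitimately be absent from a complete residue
OPTIONAL_ATOMS = frozenset({"OXT"})


@dataclass(frozen=True)
class AtomParams:
    element: str
    atom_class: str
    charge: float          # e
    eps: float             # kcal/mol
    sigma: float           # A
    radius: float          # A (vdW)
    asp: float             # kcal/(mol*A^2); file stores cal
    polar: bool


class ParameterSet:
    """Lookup of per-(residue, atom name) parameters from a versioned table."""

    def __init__(self, table: dict[tuple[str, str], AtomParams], source: str,
                 checksum: str):
        self._table = table
        self.source = source
        self.checksum = checksum

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        path = Path(path)
        raw = path.read_bytes()
        table: dict[tuple[str, str], AtomParams] = {}
        for line in raw.decode().splitlines():
            if not line or line.startswith("#"):
                continue
            res, atom, el, cl, q, eps, sig, rad, asp, polar = line.split("\t")
            table[(res, atom)] = AtomParams(
                element=el, atom_class=cl, charge=float(q), eps=float(eps),
                sigma=float(sig), radius=float(rad), asp=float(asp) / 1000.0,
                polar=bool(int(polar)))
        return cls(table, str(path), hashlib.sha256(raw).hexdigest())

    def lookup(self, residue_name: str, atom_name: str) -> AtomParams:
        try:
            return self._table[(residue_name, atom_name)]
        except KeyError:
            raise KeyError(
                f"no parameters for atom {atom_name!r} of residue "
                f"{residue_name!r} in table {self.source}") from None

    def knows_residue(self, residue_name: str) -> bool:
        return any(res == residue_name for res, _ in self._table)

    def expected_atoms(self, residue_name: str) -> list[str]:
        """Heavy atoms a complete residue of this type must carry."""
        names = [a for r, a in self._table
                 if r == residue_name and a not in OPTIONAL_ATOMS]
        if not names:
            raise KeyError(f"unknown residue type {residue_name!r}")
        return names


_DEFAULT: ParameterSet | None = None


def default_parameter_set() -> ParameterSet:
    """The parameter table shipped with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
                resources.files("anchorprobe.data") / "params_v1.tsv") as p:
            _DEFAULT = ParameterSet.from_file(p)
    return _DEFAULT
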