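"""Parsing and writing of elementary-flux-mode (EFM) files.

An EFM file is plain text with one EFM per row; each row lists the
indices of the reactions active in that EFM, whitespace-separated.  An
optional flux file of identical shape carries the relative flux of each
active reaction (same token order as the EFM row).  Most EFM-enumeration
tools emit this pair of files; indices may be 0- or 1-based depending on
the toolchain, so the base is an explicit parameter.  Internally indices
are always 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional


class EfmParseError(ValueError):
    """A token in an EFM/flux file is not interpretable."""


class EfmValidationError(ValueError):
    """Structurally readable input violating an invariant (range, shape)."""


@dataclass
class Efm:
    """One flux mode: a set of active reaction indices (1-based).

    ``relative_fluxes`` maps each active index to its flux value in the
    units the enumeration tool supplied (e.g. mmol gDW^-1 h^-1).
    """

    efm_id: int
    reaction_indices: frozenset[int]
    relative_fluxes: Optional[dict[int, float]] = None

    def __len__(self) -> int:
        return len(self.reaction_indices)

    def validate(self, n_reactions: int) -> None:
        if not self.reaction_indices:
            raise EfmValidationError(f"EFM {self.efm_id} has no reactions")
        bad = [i for i in self.reaction_indices if not 1 <= i <= n_reactions]
        if bad:
            raise EfmValidationError(
                f"EFM {self.efm_id}: reaction indices out of range "
                f"1..{n_reactions}: {sorted(bad)}"
            )
        if self.relative_fluxes is not None:
            if set(self.relative_fluxes) != set(self.reaction_indices):
                raise EfmValidationError(
                    f"EFM {self.efm_id}: flux keys do not match active "
                    "reactions"
                )
            zeros = [i for i, v in self.relative_fluxes.items() if v == 0]
            if zeros:
                raise EfmValidationError(
                    f"EFM {self.efm_id}: zero flux for active reactions "
                    f"{sorted(zeros)}"
                )


@dataclass
class EfmSet:
    """Ordered collection of EFMs addressing one model's reaction indices."""

    efms: list[Efm] = field(default_factory=list)
    model_ref: str = ""
    n_reactions: int = 0

    def __len__(self) -> int:
        return len(self.efms)

    def __iter__(self):
        return iter(self.efms)

    def by_id(self, efm_id: int) -> Efm:
        for efm in self.efms:
            if efm.efm_id == efm_id:
                return efm
        raise KeyError(f"no EFM with id {efm_id}")


def parse_efm_file(
    path: str, n_reactions: int, index_base: int = 1, model_ref: str = ""
) -> EfmSet:
    """Parse an EFM file; one Efm per non-blank row, ids are row numbers.

    ``index_base`` (0 or 1) states the convention of the file; indices
    are normalized to 1-based.  Duplicate indices within a row are
    collapsed with a warning.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if index_base not in (0, 1):
        raise ValueError("index_base must be 0 or 1")
    efms: list[Efm] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            indices: list[int] = []
            for col, tok in enumerate(tokens, start=1):
                try:
                    value = int(tok)
                    if value < 0:
                        raise ValueError
                except ValueError:
                    raise EfmParseError(
                        f"{path}: row {row_no}, column {col}: "
                        f"{tok!r} is not a nonnegative integer"
                    ) from None
                indices.append(value + (1 - index_base))
            if len(set(indices)) != len(indices):
                warnings.warn(
                    f"{path}: row {row_no}: duplicate reaction indices "
                    "collapsed",
                    stacklevel=2,
                )
            efm = Efm(efm_id=len(efms) + 1, reaction_indices=frozenset(indices))
            try:
                efm.validate(n_reactions)
            except EfmValidationError as exc:
                raise EfmValidationError(f"{path}: row {row_no}: {exc}") from None
            efms.append(efm)
    return EfmSet(efms=efms, model_ref=model_ref, n_reactions=n_reactions)


def parse_flux_file(path: str, efms: EfmSet) -> EfmSet:
    """Attach relative fluxes to an EfmSet from an aligned flux file.

    Each flux row normally carries one value per active reaction, in the
    EFM row's token order (compact form); rows whose width equals the
    model's reaction count are treated as full-length vectors instead.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                rows.append([float(t) for t in tokens])
            except ValueError:
                raise EfmParseError(
                    f"{path}: row {row_no}: non-numeric flux token"
                ) from None
    if len(rows) != len(efms):
        raise EfmValidationError(
            f"{path}: {len(rows)} flux rows for {len(efms)} EFMs"
        )
    out: list[Efm] = []
    for efm, values in zip(efms, rows):
        ordered = sorted(efm.reaction_indices)
        if len(values) == efms.n_reactions and len(ordered) != efms.n_reactions:
            # full-length vector: pick the entries at the active indices
            fluxes = {i: values[i - 1] for i in ordered}
        elif len(values) == len(ordered):
            fluxes = dict(zip(ordered, values))
        else:
            raise EfmValidationError(
                f"{path}: EFM {efm.efm_id}: {len(values)} flux values for "
                f"{len(ordered)} active reactions"
            )
        new = Efm(
            efm_id=efm.efm_id,
            reaction_indices=efm.reaction_indices,
            relative_fluxes=fluxes,
        )
        new.validate(efms.n_reactions)
        out.append(new)
    return EfmSet(efms=out, model_ref=efms.model_ref, n_reactions=efms.n_reactions)


def write_efm_file(efms: EfmSet, path: str, index_base: int = 1) -> None:
    """Serialize the EFM rows (ascending indices, space-delimited)."""
    with open(path, "w") as fh:
        for efm in efms:
            indices = sorted(efm.reaction_indices)
            fh.write(" ".join(str(i - (1 - index_base)) for i in indices) + "\n")


def write_flux_file(efms: EfmSet, path: str) -> None:
    """Serialize compact flux rows aligned with write_efm_file's order."""
    with open(path, "w") as fh:
        for efm in efms:
            if efm.relative_fluxes is None:
                raise EfmValidationError(
                    f"EFM {efm.efm_id} has no relative fluxes to write"
                )
            values = [efm.relative_fluxes[i] for i in sorted(efm.reaction_indices)]
            fh.write(" ".join(repr(v) for v in values) + "\n")
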