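"""Minimal GenePop reader/writer for diploid microsatellite genotypes.

Supports the common dialect: a title line, one locus name per line (or a
single comma-separated line), ``POP`` block separators, and individual lines
``id , 0101 0202 ...`` with 4-digit (2+2) or 6-digit (3+3) allele coding.
``0000`` / ``000000`` (or any zero allele) encodes a missing genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = ["GenepopParseError", "GenepopRecord", "read_genepop", "write_genepop"]


class GenepopParseError(ValueError):
    pass


@dataclass
class GenepopRecord:
    individual_id: str
    block: int  # 0-based POP-block index
    genotypes: tuple  # per locus: (a1, a2) ints or None for missing


def _parse_genotype(token: str, line_no: int) -> Optional[tuple[int, int]]:
    if len(token) == 4:
        a, b = token[:2], token[2:]
    elif len(token) == 6:
        a, b = token[:3], token[3:]
    else:
        raise GenepopParseError(
            f"line {line_no}: genotype token {token!r} is not 4 or 6 digits"
        )
    try:
        a_i, b_i = int(a), int(b)
    except ValueError as exc:
        raise GenepopParseError(
            f"line {line_no}: non-numeric genotype token {token!r}"
        ) from exc
    if a_i == 0 or b_i == 0:
        return None
    return (a_i, b_i)


def read_genepop(path) -> tuple[str, list[str], list[GenepopRecord]]:
    """Parse a GenePop file into (title, locus names, records)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    title = lines[0].strip()
    loci: list[str] = []
    records: list[GenepopRecord] = []
    block = -1
    for line_no, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            block += 1
            continue
        if block < 0:
            if "," in line:
                loci.extend(s.strip() for s in line.split(",") if s.strip())
            else:
                loci.append(line)
            continue
        if "," not in line:
            raise GenepopParseError(
                f"line {line_no}: expected 'id , genotypes' but found {line!r}"
            )
        ind_id, _, geno_part = line.partition(",")
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {line_no}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        genotypes = tuple(_parse_genotype(t, line_no) for t in tokens)
        records.append(
            GenepopRecord(
                individual_id=ind_id.strip(), block=block, genotypes=genotypes
            )
        )
    if block < 0:
        raise GenepopParseError("no POP block found")
    if not loci:
        raise GenepopParseError("no locus names found")
    return title, loci, records


def write_genepop(
    title: str,
    loci: Sequence[str],
    records: Sequence[GenepopRecord],
    path,
    digits: int = 3,
) -> None:
    """Write records back out; individuals are grouped by their block index."""
    if digits not in (2, 3):
        raise ValueError("allele coding must use 2 or 3 digits")
    width = digits

    def fmt(g: Optional[tuple[int, int]]) -> str:
        if g is None:
            return "0" * (2 * width)
        a, b = g
        if a >= 10**width or b >= 10**width:
            raise ValueError(f"allele too large for {width}-digit coding: {g}")
        return f"{a:0{width}d}{b:0{width}d}"

    blocks: dict[int, list[GenepopRecord]] = {}
    for rec in records:
        blocks.setdefault(rec.block, []).append(rec)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in loci:
            fh.write(locus + "\n")
        for block in sorted(blocks):
            fh.write("POP\n")
            for rec in blocks[block]:
                if len(rec.genotypes) != len(loci):
                    raise ValueError(
                        f"{rec.individual_id}: {len(rec.genotypes)} genotypes "
                        f"for {len(loci)} loci"
                    )
                geno = " ".join(fmt(g) for g in rec.genotypes)
                fh.write(f"{rec.individual_id} , {geno}\n")
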