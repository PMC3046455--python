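"""SNP definitions, catalogs and risk-allele dosage coding.

A :class:`SnpDef` describes one biallelic SNP by its two alleles, the risk
allele (the allele whose count enters the per-allele log-additive model) and
the population risk-allele frequency.  A :class:`SnpCatalog` is an ordered,
uniquely-named collection of SNPs; the packaged default catalog holds the 12
breast-cancer susceptibility variants the scanner targets (FGFR2, 8q24,
LSP1, MAP3K1, TOX3, 2q35, MRPS30, COX11, SLC4A7, CASP8, TGFB1, ESR1).
"""

from __future__ import annotations

import json
from collections.abc import Iterator, Sequence
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

from .errors import ConfigError, InvalidCallError

#: genotype-call spellings treated as missing
MISSING_CALLS = frozenset({"", "NA", "NN", "--", "00"})


@dataclass(frozen=True)
class SnpDef:
    """One biallelic SNP with a designated risk allele.

    Parameters
    ----------
    name
        Locus-rsID label, e.g. ``"10q26-rs2981582"``.  The rsID suffix names
        the dosage column in cohort tables.
    alleles
        The two alleles, e.g. ``("C", "T")``.
    risk_allele
        The allele counted by the per-allele dosage coding; must be one of
        ``alleles``.
    risk_allele_freq
        Population frequency of the risk allele, strictly inside (0, 1).
        Note this is the frequency of the *risk* allele, which may exceed
        0.5 (e.g. 2q35-rs13387042 at 0.52).
    gene_label
        Free-text gene annotation, e.g. ``"FGFR2"``.
    per_allele_or
        Per-allele odds ratio used by the cohort simulator as this SNP's
        main effect; 1.0 means no effect.
    """

    name: str
    alleles: tuple[str, str]
    risk_allele: str
    risk_allele_freq: float
    gene_label: str = ""
    per_allele_or: float = 1.0

    def __post_init__(self) -> None:
        alleles = tuple(str(a).upper() for a in self.alleles)
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "risk_allele", str(self.risk_allele).upper())
        if len(alleles) != 2 or alleles[0] == alleles[1]:
            raise ConfigError(f"{self.name}: need two distinct alleles, got {alleles}")
        if self.risk_allele not in alleles:
            raise ConfigError(
                f"{self.name}: risk allele {self.risk_allele!r} not in {alleles}"
            )
        if not 0.0 < float(self.risk_allele_freq) < 1.0:
            raise ConfigError(
                f"{self.name}: risk_allele_freq must be in (0, 1), "
                f"got {self.risk_allele_freq}"
            )
        if not float(self.per_allele_or) > 0.0:
            raise ConfigError(f"{self.name}: per_allele_or must be > 0")

    @property
    def rsid(self) -> str:
        """rsID part of the name (text after the final ``-``)."""
        return self.name.split("-")[-1]

    @property
    def other_allele(self) -> str:
        a, b = self.alleles
        return b if self.risk_allele == a else a


class SnpCatalog(Sequence):
    """Ordered collection of :class:`SnpDef` with unique names."""

    def __init__(self, snps: Sequence[SnpDef]):
        snps = tuple(snps)
        names = [s.name for s in snps]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate SNP names in catalog: {dupes}")
        self._snps = snps
        self._by_name = {s.name: s for s in snps}

    def __len__(self) -> int:
        return len(self._snps)

    def __iter__(self) -> Iterator[SnpDef]:
        return iter(self._snps)

    def __getitem__(self, i):
        if isinstance(i, str):
            return self.by_name(i)
        return self._snps[i]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self._snps)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self._snps)

    def by_name(self, name: str) -> SnpDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigError(f"unknown SNP {name!r}; catalog has {self.names}") from None

    def to_json(self, path: str | Path) -> None:
        records = [asdict(s) for s in self._snps]
        Path(path).write_text(json.dumps(records, indent=2) + "\n")

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "SnpCatalog":
        return cls([SnpDef(
            name=r["name"],
            alleles=tuple(r["alleles"]),
            risk_allele=r["risk_allele"],
            risk_allele_freq=float(r["risk_allele_freq"]),
            gene_label=r.get("gene_label", ""),
            per_allele_or=float(r.get("per_allele_or", 1.0)),
        ) for r in records])

    @classmethod
    def from_json(cls, path: str | Path) -> "SnpCatalog":
        return cls.from_records(json.loads(Path(path).read_text()))


def default_catalog() -> SnpCatalog:
    """The packaged 12-SNP breast-cancer susceptibility catalog."""
    text = resources.files("gxescan.data").joinpath("snp_catalog.json").read_text()
    return SnpCatalog.from_records(json.loads(text))


def encode_dosage(call: str | None, snp: SnpDef) -> int | None:
    """Count risk alleles in an unordered genotype call.

    ``call`` is a two-character allele pair such as ``"CT"``; missing calls
    (``None`` or any spelling in :data:`MISSING_CALLS`) propagate as ``None``.

    Raises
    ------
    InvalidCallError
        If the call contains an allele that is not one of the SNP's two
        alleles, naming both the SNP and the offending call.
    """
    if call is None:
        return None
    call = str(call).strip().upper()
    if call in MISSING_CALLS:
        return None
    if len(call) != 2:
        raise InvalidCallError(f"{snp.name}: malformed genotype call {call!r}")
    for allele in call:
        if allele not in snp.alleles:
            raise InvalidCallError(
                f"{snp.name}: allele {allele!r} in call {call!r} is not one of "
                f"{snp.alleles}"
            )
    return sum(1 for allele in call if allele == snp.risk_allele)
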