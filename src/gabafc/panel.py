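"""The GABA_A receptor subunit gene panel.

GABA_A receptors are pentameric chloride channels assembled from subunits
encoded by 19 human genes spanning eight families: alpha (GABRA1-6),
beta (GABRB1-3), gamma (GABRG1-3), delta (GABRD), epsilon (GABRE),
pi (GABRP), theta (GABRQ) and rho (GABRR1-3).  Every fractional-contribution
statistic in this package is computed over this ordered panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

from .errors import ValidationError

FAMILIES = frozenset(
    {"alpha", "beta", "gamma", "delta", "epsilon", "pi", "theta", "rho"}
)


class PanelEntry(NamedTuple):
    subunit_name: str
    gene_symbol: str
    family: str


_DEFAULT_ENTRIES: tuple[PanelEntry, ...] = tuple(
    [PanelEntry(f"alpha{i}", f"GABRA{i}", "alpha") for i in range(1, 7)]
    + [PanelEntry(f"beta{i}", f"GABRB{i}", "beta") for i in range(1, 4)]
    + [PanelEntry(f"gamma{i}", f"GABRG{i}", "gamma") for i in range(1, 4)]
    + [
        PanelEntry("delta", "GABRD", "delta"),
        PanelEntry("epsilon", "GABRE", "epsilon"),
        PanelEntry("pi", "GABRP", "pi"),
        PanelEntry("theta", "GABRQ", "theta"),
    ]
    + [PanelEntry(f"rho{i}", f"GABRR{i}", "rho") for i in range(1, 4)]
)

PANEL_SIZE = 19


@dataclass(frozen=True)
class SubunitPanel:
    """Ordered panel of the 19 GABA_A receptor subunit genes.

    The default ordering is alpha1-6, beta1-3, gamma1-3, delta, epsilon,
    pi, theta, rho1-3; all downstream tables follow it.
    """

    entries: tuple[PanelEntry, ...] = field(default=_DEFAULT_ENTRIES)

    def __post_init__(self) -> None:
        if len(self.entries) != PANEL_SIZE:
            raise ValidationError(
                f"subunit panel must have exactly {PANEL_SIZE} entries, "
                f"got {len(self.entries)}"
            )
        symbols = [e.gene_symbol for e in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValidationError("panel gene symbols must be unique")
        bad = {e.family for e in self.entries} - FAMILIES
        if bad:
            raise ValidationError(f"unknown subunit families: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        """Panel gene symbols in panel order."""
        return [e.gene_symbol for e in self.entries]

    @property
    def subunits(self) -> list[str]:
        return [e.subunit_name for e in self.entries]

    def family_of(self, gene_symbol: str) -> str:
        for e in self.entries:
            if e.gene_symbol == gene_symbol:
                return e.family
        raise KeyError(gene_symbol)

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def default_panel() -> SubunitPanel:
    """The canonical 19-gene GABA_A receptor subunit panel."""
    return SubunitPanel()
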