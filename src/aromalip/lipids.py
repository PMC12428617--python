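"""Shorthand lipid nomenclature: parsing, formatting, classification, shares.

Lipid species from untargeted LC-MS annotation arrive as compact shorthand
names such as ``TG(13:1_20:0_20:0)`` or ``SM(11:1;2O/30:3)``: a class code,
then per-chain carbons:double-bonds with optional ether prefixes (``O-``,
``P-``) and oxygenation suffixes (``;O``, ``;2O``).  ``_`` separates chains
whose sn-position is unknown, ``/`` chains with known position; a single
chain spec with no separator is a sum-composition name (total carbons and
double bonds only, e.g. ``PC(O-34:3)``).

The module parses that grammar losslessly (unrecognized suffix tokens are
preserved verbatim rather than rejected), maps class codes to the six
lipid categories (GL, GP, SP, FA, ST, PR), and aggregates relative
abundances into category/class shares and top-N key-lipid rankings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("aromalip")


class LipidParseError(ValueError):
    """Raised when a shorthand lipid name cannot be parsed."""


#: Default class-code -> category registry.  GL glycerolipids (incl. the
#: betaine lipids DGCC/DGTS and glycosyldiacylglycerols), GP
#: glycerophospholipids, SP sphingolipids (PE-Cer is a ceramide backbone,
#: so it sits here rather than under GP), FA fatty acyls, ST sterol
#: lipids, PR prenol lipids.  User registries override this wholesale.
DEFAULT_REGISTRY: dict[str, str] = {
    "MG": "GL", "DG": "GL", "TG": "GL",
    "DGCC": "GL", "DGTS": "GL", "MGDG": "GL", "DGDG": "GL", "SQDG": "GL",
    "PC": "GP", "PE": "GP", "PS": "GP", "PI": "GP", "PG": "GP", "PA": "GP",
    "LPC": "GP", "LPE": "GP", "BMP": "GP", "CL": "GP",
    "SM": "SP", "Cer": "SP", "HexCer": "SP", "Hex2Cer": "SP",
    "SHexCer": "SP", "PE-Cer": "SP", "PI-Cer": "SP", "SL": "SP",
    "FA": "FA", "FAHFA": "FA", "NAGly": "FA", "NAE": "FA", "CAR": "FA",
    "ST": "ST", "CE": "ST", "SE": "ST",
    "PR": "PR",
}

CATEGORIES = ("GL", "GP", "SP", "FA", "ST", "PR")


@dataclass(frozen=True)
class Chain:
    """One acyl/alkyl chain: carbons, double bonds, modifiers."""

    carbons: int
    double_bonds: int
    ether_prefix: str = ""          # "", "O-" or "P-"
    extra_oxygens: int = 0          # from ";O"/";2O"/";O2" suffixes
    extra_tokens: tuple[str, ...] = ()  # unrecognized suffixes, verbatim

    def __post_init__(self) -> None:
        if self.double_bonds > self.carbons:
            raise LipidParseError(
                f"chain {self.carbons}:{self.double_bonds} has more double "
                f"bonds than carbons"
            )


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed shorthand lipid name.

    ``chains`` is empty for sum-composition names; in that case the
    species-level ``ether_prefix``/``sum_*`` fields carry the information
    that would otherwise live on the chains.  ``raw_name`` keeps the input
    verbatim and is excluded from equality so that parse/format round
    trips compare structurally.
    """

    raw_name: str = field(compare=False)
    class_code: str
    category: str
    chains: tuple[Chain, ...]
    sum_carbons: int
    sum_double_bonds: int
    sum_extra_oxygens: int
    sn_positions_known: bool
    ether_prefix: str = ""
    extra_tokens: tuple[str, ...] = ()


_NAME_RE = re.compile(r"^([A-Za-z][A-Za-z0-9-]*)\((.+)\)$")
_CHAIN_RE = re.compile(r"^(O-|P-)?(\d+):(\d+)((?:;[^;_/()]+)*)$")
_OXY_N_FIRST = re.compile(r"^(\d*)O$")   # "O", "2O", "3O"
_OXY_N_LAST = re.compile(r"^O(\d+)$")    # "O2", "O3"


def _parse_chain(text: str, pos: int) -> Chain:
    m = _CHAIN_RE.match(text)
    if m is None:
        raise LipidParseError(
            f"malformed chain spec {text!r} at character {pos}"
        )
    prefix, carbons, dbonds, suffix = m.groups()
    oxy = 0
    extra: list[str] = []
    for token in filter(None, suffix.split(";")):
        mt = _OXY_N_FIRST.match(token) or _OXY_N_LAST.match(token)
        if mt is not None:
            oxy += int(mt.group(1) or 1)
        else:
            extra.append(token)
    return Chain(
        carbons=int(carbons),
        double_bonds=int(dbonds),
        ether_prefix=prefix or "",
        extra_oxygens=oxy,
        extra_tokens=tuple(extra),
    )


def parse_lipid(name: str, registry: dict[str, str] | None = None,
                lenient: bool = False) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Whitespace anywhere in the name is treated as typography and removed
    (printed names often read ``TG(13: 1_20: 0_20: 0)``).  With
    ``lenient=True`` an unregistered class code is assigned category
    ``"unknown"`` instead of raising.
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    clean = re.sub(r"\s+", "", str(name))
    m = _NAME_RE.match(clean)
    if m is None:
        raise LipidParseError(f"cannot parse lipid name {name!r}")
    code, body = m.groups()
    if code not in registry:
        if lenient:
            category = "unknown"
        else:
            raise LipidParseError(
                f"unknown lipid class code {code!r}; registered codes: "
                f"{', '.join(sorted(registry))}"
            )
    else:
        category = registry[code]

    parts = re.split(r"([_/])", body)
    chain_texts = parts[0::2]
    seps = set(parts[1::2])
    sn_known = seps == {"/"}

    offset = len(code) + 1
    chains = []
    for text in chain_texts:
        chains.append(_parse_chain(text, clean.index(text, offset)))
        offset += len(text) + 1

    if len(chains) == 1 and not seps:
        c = chains[0]
        return LipidSpecies(
            raw_name=name, class_code=code, category=category, chains=(),
            sum_carbons=c.carbons, sum_double_bonds=c.double_bonds,
            sum_extra_oxygens=c.extra_oxygens, sn_positions_known=False,
            ether_prefix=c.ether_prefix, extra_tokens=c.extra_tokens,
        )
    return LipidSpecies(
        raw_name=name, class_code=code, category=category,
        chains=tuple(chains),
        sum_carbons=sum(c.carbons for c in chains),
        sum_double_bonds=sum(c.double_bonds for c in chains),
        sum_extra_oxygens=sum(c.extra_oxygens for c in chains),
        sn_positions_known=sn_known,
        extra_tokens=tuple(t for c in chains for t in c.extra_tokens),
    )


def _format_suffix(extra_oxygens: int, extra_tokens: tuple[str, ...]) -> str:
    out = ""
    if extra_oxygens == 1:
        out += ";O"
    elif extra_oxygens > 1:
        out += f";{extra_oxygens}O"
    for t in extra_tokens:
        out += f";{t}"
    return out


def format_lipid(species: LipidSpecies) -> str:
    """Canonical space-free shorthand; ``parse_lipid(format_lipid(x)) == x``.

    Oxygenation counts are normalized to the digit-first dialect
    (``;2O``), so formatting is canonicalizing, not byte-preserving.
    """
    if not species.chains:
        body = (
            f"{species.ether_prefix}{species.sum_carbons}:"
            f"{species.sum_double_bonds}"
            + _format_suffix(species.sum_extra_oxygens, species.extra_tokens)
        )
        return f"{species.class_code}({body})"
    sep = "/" if species.sn_positions_known else "_"
    body = sep.join(
        f"{c.ether_prefix}{c.carbons}:{c.double_bonds}"
        + _format_suffix(c.extra_oxygens, c.extra_tokens)
        for c in species.chains
    )
    return f"{species.class_code}({body})"


def categorize(class_code: str, registry: dict[str, str] | None = None,
               lenient: bool = False) -> str:
    """Map a class code to its lipid category under the active registry."""
    registry = DEFAULT_REGISTRY if registry is None else registry
    if class_code not in registry:
        if lenient:
            return "unknown"
        raise KeyError(
            f"unregistered lipid class code {class_code!r}; known codes: "
            f"{', '.join(sorted(registry))}"
        )
    return registry[class_code]


#: The 14 key species reported for 3-year dry-cured ham, used as the
#: parser's reference corpus and as the default key-lipid panel.
KEY_HAM_LIPIDS: tuple[str, ...] = (
    "TG(13:1_20:0_20:0)",
    "TG(O-8:0_14:0_14:1)",
    "TG(8:0_18:1_26:1)",
    "DG(O-15:1_20:3)",
    "PC(O-34:3)",
    "SM(11:1;2O/30:3)",
    "Cer(15:1;2O/26:5)",
    "SHexCer(37:1;2O)",
    "FAHFA(20:4/18:0)",
    "NAGly(16:0/18:1)",
    "PE-Cer(14:3;2O/23:1;O)",
    "DGCC(23:0_22:2)",
    "DGCC(18:0_30:0)",
    "ST(24:1;O3;T/20:1)",
)


def class_shares(table: pd.DataFrame, level: str = "class_code",
                 registry: dict[str, str] | None = None) -> pd.DataFrame:
    """Abundance share and species count per class code or category.

    ``table`` is species × samples (index = shorthand names).  Shares are
    percentages of total mean abundance (mean over samples), and sum to
    100 across groups.
    """
    if level not in ("category", "class_code"):
        raise ValueError("level must be 'category' or 'class_code'")
    parsed = [parse_lipid(n, registry=registry) for n in table.index]
    groups = [getattr(s, level) for s in parsed]
    means = table.mean(axis=1, skipna=True)
    df = pd.DataFrame({"group": groups, "mean_abundance": means.to_numpy()})
    agg = df.groupby("group").agg(
        n_species=("group", "size"), total=("mean_abundance", "sum")
    )
    agg["share_percent"] = 100.0 * agg["total"] / agg["total"].sum()
    agg = agg.drop(columns="total").sort_values(
        "share_percent", ascending=False
    )
    agg.index.name = level
    return agg.reset_index()


def select_key_lipids(table: pd.DataFrame, top_n: int = 14,
                      method: str = "mean_abundance") -> pd.DataFrame:
    """Rank species by mean relative abundance and keep the top ``top_n``.

    Deterministic tie-break on species name.  ``top_n`` beyond the species
    count returns everything with a warning.
    """
    if method != "mean_abundance":
        raise ValueError(f"unknown ranking method {method!r}")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    means = table.mean(axis=1, skipna=True)
    ranked = (
        pd.DataFrame({"lipid": means.index, "mean_abundance": means.to_numpy()})
        .sort_values(["mean_abundance", "lipid"], ascending=[False, True])
        .reset_index(drop=True)
    )
    ranked.insert(0, "rank", range(1, len(ranked) + 1))
    if top_n > len(ranked):
        logger.warning(
            "top_n=%d exceeds species count %d; returning all",
            top_n, len(ranked),
        )
        return ranked
    return ranked.head(top_n)
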