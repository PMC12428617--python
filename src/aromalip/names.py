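"""Compound-name canonicalization.

GC-MS library hits come back under systematic names ("Butanoic acid, ethyl
ester") while odor-threshold literature mostly uses trivial names ("ethyl
butyrate").  Joining a peak table against a threshold database therefore
needs a single canonical key per compound: case-folded, whitespace-collapsed
and mapped through a synonym table.
"""

from __future__ import annotations

import re

# alias (canonical-cased) -> trivial name used as the canonical key
SYNONYMS: dict[str, str] = {
    "valeraldehyde": "pentanal",
    "n-valeraldehyde": "pentanal",
    "n-pentanal": "pentanal",
    "n-hexanal": "hexanal",
    "n-heptanal": "heptanal",
    "n-octanal": "octanal",
    "n-nonanal": "nonanal",
    "isopropyl alcohol": "isopropanol",
    "2-butanol": "sec-butanol",
    "2-butyl alcohol": "sec-butanol",
    "1-octene-3-ol": "1-octen-3-ol",
    "n-heptanol": "1-heptanol",
    "heptan-1-ol": "1-heptanol",
    "4-heptanol, 2,6-dimethyl-": "2,6-dimethyl-4-heptanol",
    "5-hepten-2-ol, 6-methyl-": "6-methyl-5-hepten-2-ol",
    "(±)-6-methyl-5-hepten-2-ol": "6-methyl-5-hepten-2-ol",
    "benzenemethanol": "benzyl alcohol",
    "1-octene-3-one": "1-octen-3-one",
    "butanoic acid, ethyl ester": "ethyl butyrate",
    "butanoic acid, 2-methyl-, ethyl ester": "ethyl 2-methylbutyrate",
    "butanoic acid, 3-methyl-, ethyl ester": "ethyl 3-methylbutyrate",
    "hexanoic acid, ethyl ester": "ethyl hexanoate",
    "acetic acid, 2-phenylethyl ester": "phenethyl acetate",
    "phenylethyl acetate": "phenethyl acetate",
    "hexadecanoic acid, ethyl ester": "ethyl palmitate",
    "octanoic acid, methyl ester": "methyl octanoate",
    "tetradecanoic acid": "myristic acid",
    "n-hexadecanoic acid": "palmitic acid",
    "hexadecanoic acid": "palmitic acid",
    "ethanone, 1-(1h-pyrrol-2-yl)-": "1-(1h-pyrrol-2-yl)ethanone",
    "ethanone, 1-(1h-pyrrole-2-yl)-": "1-(1h-pyrrol-2-yl)ethanone",
}


def _basic(name: str) -> str:
    # locant commas ("2,6-dimethyl") stay tight; name-part commas
    # ("butanoic acid, ethyl ester") get a single following space
    key = re.sub(r"\s+", " ", str(name)).strip().casefold()
    key = re.sub(r"\s*,\s*", ",", key)
    return re.sub(r",(?=[a-z])", ", ", key)


_SYNONYMS_NORM = {_basic(k): v for k, v in SYNONYMS.items()}


def canonicalize(name: str) -> str:
    """Return the canonical key for a compound name.

    Case-folds, trims, collapses internal whitespace, normalizes spacing
    around commas (tight before digits, spaced before letters), then
    resolves known synonyms to their trivial name.
    """
    key = _basic(name)
    return _SYNONYMS_NORM.get(key, key)
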