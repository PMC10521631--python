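"""Peptide sequence tokenization, masses and additive scalar descriptors.

Modified peptide sequences from different search engines are mapped onto one
closed token vocabulary: the 20 canonical amino acids, six modified residues
(phospho-S/T/Y, carbamidomethyl- and cysteinyl-C, oxidized M), two start
tokens (plain / N-terminally acetylated), an end token and a padding token.
The canonical in-memory representation of a sequence is the space-separated
token string, e.g. ``<START> P E P S-ph I D E <END>``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

from pyteomics import mass as _pt_mass

# canonical residue tokens: "X" or "X-mod"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

MODIFIED_RESIDUES = ("S-ph", "T-ph", "Y-ph", "C-cam", "C-cys", "M-ox")

PAD, START, START_AC, END = "<PAD>", "<START>", "<START-ac>", "<END>"

# monoisotopic modification mass deltas, Da
MOD_DELTAS = {
    "ph": 79.96633,
    "ac": 42.01057,
    "cam": 57.02146,
    "ox": 15.99491,
    "cys": 119.00410,
}

PROTON_MASS = 1.007276
WATER_MASS = 18.0105646863

# residues a given modification may sit on
_MOD_SITES = {"ph": "STY", "cam": "C", "cys": "C", "ox": "M"}

# MaxQuant-style lowercase tags -> canonical mod ids
_MQ_MODS = {"ph": "ph", "ox": "ox", "ac": "ac", "ca": "cam", "cam": "cam", "cys": "cys"}

# PEAKS-style mass-delta tags, matched to 2 decimals
_PEAKS_DELTAS = {
    "79.97": "ph",
    "79.96": "ph",
    "42.01": "ac",
    "57.02": "cam",
    "15.99": "ox",
    "119.00": "cys",
}


class TokenizationError(ValueError):
    """Raised when a raw sequence contains an unknown residue or modification."""


@dataclass(frozen=True)
class TokenVocab:
    """Ordered closed vocabulary with a bijective token <-> index map."""

    tokens: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        if self.tokens[0] != PAD:
            raise ValueError("padding token must sit at index 0")
        if len(self.tokens) > 64:
            raise ValueError("vocabulary exceeds 64 tokens")

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, token_string: str) -> list[int]:
        try:
            return [self.index[t] for t in token_string.split()]
        except KeyError as e:
            raise TokenizationError(f"token not in vocabulary: {e.args[0]}") from None


def default_vocab() -> TokenVocab:
    return TokenVocab(
        (PAD, START, START_AC, END) + tuple(AMINO_ACIDS) + MODIFIED_RESIDUES
    )


_VOCAB = default_vocab()
_RESIDUE_TOKENS = set(AMINO_ACIDS) | set(MODIFIED_RESIDUES)


def _residue_token(aa: str, mod: str | None, raw: str) -> str:
    if aa not in AMINO_ACIDS:
        raise TokenizationError(f"unknown residue {aa!r} in {raw!r}")
    if mod is None:
        return aa
    sites = _MOD_SITES.get(mod)
    if sites is None or aa not in sites:
        raise TokenizationError(f"modification {mod!r} not allowed on {aa!r} in {raw!r}")
    return f"{aa}-{mod}"


def _parse_maxquant(raw: str) -> list[str]:
    body = raw.strip().strip("_")
    tokens: list[str] = [START]
    i = 0
    if body.startswith("("):  # N-terminal tag, e.g. (ac)
        j = body.index(")") if ")" in body else -1
        if j < 0:
            raise TokenizationError(f"unbalanced parenthesis in {raw!r}")
        tag = body[1:j].lower()
        if _MQ_MODS.get(tag) != "ac":
            raise TokenizationError(f"unknown N-terminal modification {tag!r} in {raw!r}")
        tokens = [START_AC]
        i = j + 1
    out = tokens
    while i < len(body):
        aa = body[i]
        i += 1
        mod = None
        if i < len(body) and body[i] == "(":
            j = body.find(")", i)
            if j < 0:
                raise TokenizationError(f"unbalanced parenthesis in {raw!r}")
            tag = body[i + 1 : j].lower()
            if tag not in _MQ_MODS:
                raise TokenizationError(f"unknown modification {tag!r} in {raw!r}")
            mod = _MQ_MODS[tag]
            i = j + 1
        out.append(_residue_token(aa.upper(), mod, raw))
    out.append(END)
    return out


_PEAKS_TAG = re.compile(r"\(([+-]\d+(?:\.\d+)?)\)")


def _parse_peaks(raw: str) -> list[str]:
    body = raw.strip()
    tokens: list[str] = [START]
    i = 0
    m = _PEAKS_TAG.match(body)
    if m:  # leading delta = N-terminal acetylation
        if _peaks_mod(m.group(1), raw) != "ac":
            raise TokenizationError(f"unknown N-terminal delta in {raw!r}")
        tokens = [START_AC]
        i = m.end()
    while i < len(body):
        aa = body[i]
        i += 1
        mod = None
        m = _PEAKS_TAG.match(body, i)
        if m:
            mod = _peaks_mod(m.group(1), raw)
            i = m.end()
        tokens.append(_residue_token(aa.upper(), mod, raw))
    tokens.append(END)
    return tokens


def _peaks_mod(delta: str, raw: str) -> str:
    key = f"{abs(float(delta)):.2f}"
    if key not in _PEAKS_DELTAS:
        raise TokenizationError(f"unknown mass delta {delta!r} in {raw!r}")
    return _PEAKS_DELTAS[key]


def _parse_canonical(raw: str) -> list[str]:
    body = raw.strip()
    if body.startswith("<"):  # already a space-separated token string
        toks = body.split()
        if toks[0] not in (START, START_AC) or toks[-1] != END:
            raise TokenizationError(f"malformed token string {raw!r}")
        for t in toks[1:-1]:
            if t not in _RESIDUE_TOKENS:
                raise TokenizationError(f"unknown token {t!r} in {raw!r}")
        return toks
    # compact canonical form uses MaxQuant-like "(mod)" tags without underscores
    return _parse_maxquant(body)


_DIALECTS = {
    "maxquant": _parse_maxquant,
    "peaks": _parse_peaks,
    "canonical": _parse_canonical,
}


def tokenize(raw: str, dialect: str = "canonical") -> str:
    """Convert a raw sequence to the canonical space-separated token string.

    Raises :class:`TokenizationError` for residues or modifications outside
    the closed vocabulary, naming the offending span.
    """
    if not raw or not raw.strip():
        raise TokenizationError("empty sequence")
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    tokens = _DIALECTS[dialect](raw)
    if len(tokens) < 3:
        raise TokenizationError(f"no residues in {raw!r}")
    return " ".join(tokens)


def detokenize(token_string: str) -> str:
    """Render the compact canonical text form, e.g. ``(ac)M(ox)AAK``."""
    toks = token_string.split()
    out = []
    if toks and toks[0] == START_AC:
        out.append("(ac)")
    for t in toks:
        if t in (START, START_AC, END, PAD):
            continue
        if "-" in t:
            aa, mod = t.split("-")
            out.append(f"{aa}({mod})")
        else:
            out.append(t)
    return "".join(out)


_PEAKS_RENDER = {"ph": "+79.97", "ox": "+15.99", "cam": "+57.02", "cys": "+119.00"}


def render(token_string: str, dialect: str) -> str:
    """Render the canonical token string in a source dialect's text form."""
    if dialect == "canonical":
        return detokenize(token_string)
    if dialect == "maxquant":
        return f"_{detokenize(token_string)}_"
    if dialect == "peaks":
        toks = token_string.split()
        out = ["(+42.01)"] if toks and toks[0] == START_AC else []
        for t in toks:
            if t in (START, START_AC, END, PAD):
                continue
            if "-" in t:
                aa, mod = t.split("-")
                out.append(f"{aa}({_PEAKS_RENDER[mod]})")
            else:
                out.append(t)
        return "".join(out)
    raise ValueError(f"unknown dialect {dialect!r}")


def residue_tokens(token_string: str) -> list[str]:
    """Residue tokens only (terminals and padding stripped)."""
    return [t for t in token_string.split() if t in _RESIDUE_TOKENS]


def monoisotopic_mass(token_string: str) -> float:
    """Monoisotopic peptide mass in Da: residues + water + modification deltas."""
    toks = token_string.split()
    total = WATER_MASS
    for t in toks:
        if t in (START, END, PAD):
            continue
        if t == START_AC:
            total += MOD_DELTAS["ac"]
        elif "-" in t:
            aa, mod = t.split("-")
            total += _pt_mass.std_aa_mass[aa] + MOD_DELTAS[mod]
        else:
            total += _pt_mass.std_aa_mass[t]
    return total


def mz(mass: float, charge: int) -> float:
    """Mass-to-charge ratio in Th for a protonated ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


SCALE_NAMES = (
    "volume",
    "polarity",
    "hydropathy",
    "hydrophilicity",
    "solvent_exposed_area",
    "accessible_surface_area",
    "accessible_surface_area_folded",
    "local_flexibility",
    "pk_side_chain",
)


def load_descriptor_table() -> dict[str, dict[str, float]]:
    """Nine per-amino-acid scalar scales, pinned as package data.

    Returns a mapping scale name -> {amino acid -> value}; every scale covers
    all 20 canonical residues.
    """
    table: dict[str, dict[str, float]] = {name: {} for name in SCALE_NAMES}
    path = resources.files("ccspred").joinpath("data/descriptors.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["scale_name"]][row["amino_acid"]] = float(row["value"])
    for name, scale in table.items():
        missing = set(AMINO_ACIDS) - set(scale)
        if missing:
            raise ValueError(f"descriptor scale {name} missing {sorted(missing)}")
    return table


_DESCRIPTORS: dict[str, dict[str, float]] | None = None


def scalar_descriptors(token_string: str, table=None) -> dict[str, float]:
    """Length-normalized additive descriptors of a peptide sequence.

    Each of the nine scales is summed over residues (modified residues use
    their base amino acid's value) and divided by the residue count.
    """
    global _DESCRIPTORS
    if table is None:
        if _DESCRIPTORS is None:
            _DESCRIPTORS = load_descriptor_table()
        table = _DESCRIPTORS
    residues = residue_tokens(token_string)
    if not residues:
        raise ValueError("sequence has no residues")
    bases = [t.split("-")[0] for t in residues]
    n = len(bases)
    return {name: sum(scale[aa] for aa in bases) / n for name, scale in table.items()}
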