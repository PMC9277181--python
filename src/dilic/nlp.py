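"""Lightweight NLP primitives: sentence segmentation, tokenization,
noun/adjective tagging, plural lemmatization and Porter stemming.

These are deliberately small, rule-based components tuned for biomedical
titles and abstracts.  The pipeline only needs to (a) split sentences
without breaking on common abbreviations, (b) keep content words that are
nouns or adjectives, and (c) map inflected forms of the same word to one
canonical string.  A full statistical tagger buys little here because the
downstream features are bag-of-keyword-set counts, not parses.
"""

from __future__ import annotations

import re
from functools import lru_cache

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

#: Default English stop-word list (scikit-learn's built-in list).
DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)

# Abbreviations whose trailing period does not end a sentence.
_ABBREVIATIONS = {
    "fig", "figs", "eq", "eqs", "ref", "refs", "tab", "no", "nos",
    "e.g", "i.e", "cf", "vs", "etc", "et", "al", "ca", "approx",
    "dr", "prof", "mr", "mrs", "ms", "st", "inc", "ltd", "wk", "yr",
    "mo", "hr", "min", "sec", "resp", "spp", "sp", "var", "viz",
}

_SENT_BOUNDARY = re.compile(r"([.!?]+)(\s+)")

_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-]*[A-Za-z0-9]|[A-Za-z0-9]")


def segment_sentences(text: str) -> list[str]:
    """Split free text into sentences.

    Periods after known abbreviations (``Fig.``, ``e.g.``, ``et al.``),
    after single initials, and inside decimal numbers are not treated as
    boundaries.  The concatenation of the returned sentences preserves
    every non-whitespace character of the input in order.
    """
    if not text or not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        end = m.end(1)
        before = text[start:m.start(1)]
        # last word before the terminator, without surrounding brackets
        last = before.rstrip().rsplit(None, 1)[-1].strip("()[]\"'") if before.strip() else ""
        if m.group(1) == ".":
            low = last.lower().rstrip(".")
            if low in _ABBREVIATIONS or (len(last) == 1 and last.isalpha()):
                continue  # abbreviation or initial
            nxt = text[m.end():m.end() + 1]
            if last[-1:].isdigit() and nxt.isdigit():
                continue  # decimal number split across whitespace — keep
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def word_tokenize(sentence: str) -> list[str]:
    """Extract word tokens (letters/digits, internal hyphens and apostrophes kept)."""
    return _TOKEN_RE.findall(sentence)


# ---------------------------------------------------------------------------
# Part-of-speech classification (NOUN / ADJ / OTHER)
# ---------------------------------------------------------------------------

# Frequent verbs and participles in abstracts; tagged OTHER.
_VERBS = {
    "be", "is", "are", "was", "were", "been", "being", "am",
    "has", "have", "had", "having", "do", "does", "did", "done",
    "observed", "observe", "observes", "observing",
    "showed", "show", "shows", "shown", "showing",
    "demonstrated", "demonstrate", "demonstrates", "demonstrating",
    "reported", "report", "reports", "reporting",
    "found", "find", "finds", "suggest", "suggests", "suggested",
    "indicate", "indicates", "indicated", "indicating",
    "associated", "associate", "correlate", "correlated",
    "used", "use", "uses", "using", "performed", "perform", "performs",
    "conducted", "conduct", "measured", "measure", "measures",
    "compared", "compare", "compares", "comparing",
    "treated", "treat", "treats", "treating",
    "administered", "administer", "received", "receive", "receives",
    "occurred", "occur", "occurs", "developed", "develop", "develops",
    "included", "include", "includes", "including",
    "revealed", "reveal", "reveals", "evaluated", "evaluate", "evaluates",
    "identified", "identify", "identifies", "assessed", "assess",
    "analyzed", "analyze", "analyzes", "investigated", "investigate",
    "presented", "present", "presents", "described", "describe",
    "caused", "cause", "causes", "causing", "resolved", "resolve", "resolves",
    "remains", "remain", "remained", "became", "become", "becomes",
    "underwent", "undergo", "may", "might", "can", "could", "should",
    "would", "will", "shall", "must",
}

# Adjectives the suffix rules miss.
_ADJ_LEXICON = {
    "elderly", "early", "severe", "acute", "mild", "adverse", "high",
    "low", "higher", "lower", "highest", "lowest", "new", "old",
    "large", "small", "larger", "smaller", "common", "rare", "major",
    "minor", "normal", "abnormal", "safe", "human", "male", "female",
    "oral", "renal", "liver", "long-term", "short-term", "frequent",
    "broad", "wide", "deep", "late", "good", "bad", "poor",
}

_ADJ_SUFFIXES = (
    "al", "ic", "ous", "ive", "ary", "ory", "able", "ible",
    "ful", "less", "ish", "oid", "like", "ant", "ent",
)

# Noun suffixes that override the -ed / -ing verb heuristics
# ("finding", "screening") and the -ant/-ent adjective suffixes
# ("patient", "infant", "agent" stay nouns via this exception list).
_NOUN_EXCEPTIONS = {
    "patient", "patients", "agent", "agents", "infant", "infants",
    "event", "events", "treatment", "treatments", "assessment",
    "management", "development", "environment", "measurement",
    "department", "content", "extent", "antioxidant", "antioxidants",
    "finding", "findings", "screening", "screenings", "imaging",
    "monitoring", "dosing", "setting", "settings", "meaning",
    "drug", "drugs", "injury", "injuries",
}

NOUN = "NOUN"
ADJ = "ADJ"
OTHER = "OTHER"


def pos_tag(token: str) -> str:
    """Classify a token as NOUN, ADJ, or OTHER (universal-POS flavour;
    proper nouns count as nouns, which keeps drug names).

    Rule order matters: lexicons first, then adverb/verb suffixes, then
    adjective suffixes; anything left — including out-of-vocabulary
    technical terms — defaults to NOUN.
    """
    low = token.lower()
    if not any(c.isalpha() for c in low):
        return OTHER  # pure numbers
    if low in DEFAULT_STOPWORDS:
        return OTHER
    if low in _NOUN_EXCEPTIONS:
        return NOUN
    if low in _ADJ_LEXICON:
        return ADJ
    if low in _VERBS:
        return OTHER
    if "-" in low:
        # hyphenated modifiers: "drug-induced", "dose-dependent"
        return ADJ
    if low.endswith("ly"):
        return OTHER  # adverbs
    if low.endswith(("ed", "ing")) and len(low) > 4:
        return OTHER  # verb participles
    if low.endswith(_ADJ_SUFFIXES):
        return ADJ
    return NOUN


# ---------------------------------------------------------------------------
# Lemmatization (noun plurals) and Porter stemming
# ---------------------------------------------------------------------------

_IRREGULAR_PLURALS = {
    "men": "man", "women": "woman", "children": "child", "people": "person",
    "mice": "mouse", "feet": "foot", "teeth": "tooth", "data": "datum",
    "criteria": "criterion", "phenomena": "phenomenon", "analyses": "analysis",
    "diagnoses": "diagnosis", "hypotheses": "hypothesis", "fungi": "fungus",
}


def lemmatize(token: str) -> str:
    """Reduce a lowercased token to a singular base form (rule-based)."""
    if token in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[token]
    if len(token) > 3 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 3 and token.endswith(("ches", "shes", "xes", "zes", "sses")):
        return token[:-2]
    if len(token) > 2 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Porter's m: the number of VC sequences in [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        vowel = not _is_consonant(stem, i)
        if prev_vowel and not vowel:
            m += 1
        prev_vowel = vowel
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


@lru_cache(maxsize=65536)
def porter_stem(word: str) -> str:
    """Classic Porter stemming algorithm (steps 1a–5b)."""
    w = word
    if len(w) <= 2:
        return w

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b
    flag_1b = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed"):
        if _contains_vowel(w[:-2]):
            w = w[:-2]
            flag_1b = True
    elif w.endswith("ing"):
        if _contains_vowel(w[:-3]):
            w = w[:-3]
            flag_1b = True
    if flag_1b:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_consonant(w) and not w.endswith(("l", "s", "z")):
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"

    # Step 1c
    if w.endswith("y") and _contains_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    step2 = [
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
        ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
        ("alli", "al"), ("entli", "ent"), ("eli", "e"), ("ousli", "ous"),
        ("ization", "ize"), ("ation", "ate"), ("ator", "ate"),
        ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"),
        ("biliti", "ble"),
    ]
    for suf, repl in step2:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 3
    step3 = [
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ]
    for suf, repl in step3:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 4
    step4 = [
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ]
    for suf in step4:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if suf == "ion" and not stem.endswith(("s", "t")):
                break
            if _measure(stem) > 1:
                w = stem
            break

    # Step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # Step 5b
    if _ends_double_consonant(w) and w.endswith("l") and _measure(w) > 1:
        w = w[:-1]

    return w


def normalize_token(token: str) -> str:
    """Canonical normalization used everywhere: lowercase → lemmatize → stem."""
    return porter_stem(lemmatize(token.lower()))
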