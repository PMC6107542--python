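"""Regex-based extraction of effect-size estimates from abstract text.

Abstracts reporting observational results usually print an effect measure
(odds ratio, relative risk, hazard ratio, rate ratio), a point estimate, and
parenthesized uncertainty — a confidence interval or a p-value. This module
scans plain text for that composite pattern, derives a log-scale standard
error from the CI (preferred) or the p-value, and supports the
estimate-versus-SE scatter used to visualize publication bias: estimates whose
CI excludes 1 lie below the line se = |log estimate| / 1.96, and a corpus with
pervasive publication bias shows a sharp boundary there.

Because printed numbers are rounded, scatter plots of raw extractions show
banding artefacts; ``jitter_for_plot`` adds uniform noise within the half-unit
of the last printed digit so that every jittered number still rounds back to
the printed one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = ["LiteratureEstimate", "extract_estimates", "se_from_uncertainty",
           "jitter_for_plot", "jitter_value"]

NUMBER = r"[0-9][0-9]?[0-9]?\.[0-9][0-9]?[0-9]?"
P_VALUE = r"p ?[<=>] ?0?\.[0-9][0-9]?[0-9]?"
CI = NUMBER + r" ?(?:-|to|,) ?" + NUMBER

# effect-measure phrases; the bare tokens "or"/"hr"/"rr" are prone to false
# positives, hence the strict variant with word boundaries and escaped dots
_EM_PHRASES = r"odds ratio|o.r.|or|relative risk|r.r.|rr|hazard ratio|h.r.|hr|hazard|rate ratio"
_EM_PHRASES_STRICT = (r"odds ratio|o\.r\.|\bor\b|relative risk|r\.r\.|\brr\b"
                      r"|hazard ratio|h\.r\.|\bhr\b|hazard|rate ratio")

_EFFECT_TYPE = {
    "odds ratio": "odds ratio", "o.r.": "odds ratio", "or": "odds ratio",
    "relative risk": "relative risk", "r.r.": "relative risk", "rr": "relative risk",
    "hazard ratio": "hazard ratio", "h.r.": "hazard ratio", "hr": "hazard ratio",
    "hazard": "hazard ratio", "rate ratio": "rate ratio",
}

_DASHES = dict.fromkeys(map(ord, "‒–—―−"), "-")

_CI_RE = re.compile(rf"(?P<cil>{NUMBER}) ?(?:-|to|,) ?(?P<ciu>{NUMBER})")


def _composite(strict: bool) -> re.Pattern:
    phrases = _EM_PHRASES_STRICT if strict else _EM_PHRASES
    def em(i: int) -> str:
        return (rf"(?P<phrase{i}>{phrases})(?:[^0-9a-z]*| is | of )"
                rf"(?P<value{i}>{NUMBER})")
    pval = rf"p ?(?P<pop>[<=>]) ?(?P<pnum>0?\.[0-9][0-9]?[0-9]?)"
    ci = rf"(?P<cil>{NUMBER}) ?(?:-|to|,) ?(?P<ciu>{NUMBER})"
    pattern = (r"(?:" + em(1) + r" ?\(|\([^)]*" + em(2) + r")"
               r"[^(]*(?:" + pval + r"|" + ci + r")[^(]*\)")
    return re.compile(pattern)


@dataclass
class LiteratureEstimate:
    """One effect estimate mined from text, with its printed strings retained."""

    effect_type: str
    value: float
    value_str: str
    ci: tuple[float, float] | None = None
    ci_strs: tuple[str, str] | None = None
    p: float | None = None
    p_operator: str | None = None
    p_str: str | None = None
    se_log: float | None = None
    source_span: tuple[int, int] = (0, 0)
    flags: list[str] = field(default_factory=list)


def extract_estimates(text: str, strict: bool = False) -> list[LiteratureEstimate]:
    """All effect estimates matched in ``text`` (case-insensitive, idempotent).

    A match is an effect-measure phrase and number followed by a
    parenthesized CI or p-value (or a parenthetical containing both the
    phrase and the uncertainty). No match yields an empty list.
    """
    normalized = text.lower().translate(_DASHES)
    out: list[LiteratureEstimate] = []
    for m in _composite(strict).finditer(normalized):
        phrase = m.group("phrase1") or m.group("phrase2")
        value_str = m.group("value1") or m.group("value2")
        est = LiteratureEstimate(
            effect_type=_EFFECT_TYPE.get(phrase.strip(), phrase.strip()),
            value=float(value_str), value_str=value_str,
            source_span=m.span())
        if m.group("cil") is not None:
            est.ci = (float(m.group("cil")), float(m.group("ciu")))
            est.ci_strs = (m.group("cil"), m.group("ciu"))
        elif m.group("pnum") is not None:
            est.p = float("0" + m.group("pnum").lstrip("0"))
            est.p_operator = m.group("pop")
            est.p_str = m.group("pnum")
            # the CI takes precedence when the parenthetical reports both;
            # rescan the match with the p-value segment blanked out
            value_end = m.end("value1") if m.group("value1") else m.end("value2")
            before = normalized[value_end:m.start("pnum")]
            after = normalized[m.end("pnum"):m.end()]
            cm = _CI_RE.search(before) or _CI_RE.search(after)
            if cm:
                est.ci = (float(cm.group("cil")), float(cm.group("ciu")))
                est.ci_strs = (cm.group("cil"), cm.group("ciu"))
        if est.ci is not None and not (est.ci[0] <= est.value <= est.ci[1]):
            est.flags.append("estimate outside its CI")
        out.append(est)
    return out


def se_from_uncertainty(estimate: LiteratureEstimate) -> LiteratureEstimate:
    """Attach the log-scale standard error derived from the CI or p-value.

    From a CI: se = (log upper - log lower) / (2 * 1.96). From a two-sided
    normal p-value: se = |log value| / Phi^-1(1 - p/2). The CI takes
    precedence when both are present. Degenerate inputs (inverted CI,
    non-positive bound, p of 0 or 1, value exactly 1 with only a p-value)
    leave se absent and add a flag.
    """
    est = replace(estimate, flags=list(estimate.flags))
    if est.ci is not None:
        lo, hi = est.ci
        if lo <= 0 or hi <= 0 or hi < lo:
            est.flags.append("unusable CI")
            return est
        est.se_log = float((np.log(hi) - np.log(lo)) / (2.0 * 1.959963984540054))
        return est
    if est.p is not None:
        if est.p <= 0.0 or est.p >= 1.0:
            est.flags.append("unusable p-value")
            return est
        z = stats.norm.ppf(1.0 - est.p / 2.0)
        if est.value <= 0 or np.log(est.value) == 0.0 or z <= 0:
            est.flags.append("se undefined from p-value")
            return est
        est.se_log = float(abs(np.log(est.value)) / z)
        return est
    est.flags.append("no uncertainty reported")
    return est


def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def jitter_value(value: float, printed: str, rng: np.random.Generator,
                 eps: float = 1e-9) -> float:
    """Uniform draw within the half-unit-in-last-digit interval of ``printed``.

    The draw always rounds back to the printed value, e.g. 1.5 maps into
    [1.450000001, 1.549999999].
    """
    half = 0.5 * 10.0 ** (-_decimals(printed))
    return float(rng.uniform(value - half + eps, value + half - eps))


def jitter_for_plot(estimate: LiteratureEstimate, seed: int | np.random.Generator
                    ) -> LiteratureEstimate:
    """Copy of ``estimate`` with value, CI and p-value jittered within rounding."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    est = replace(estimate, flags=list(estimate.flags))
    est.value = jitter_value(est.value, est.value_str, rng)
    if est.ci is not None and est.ci_strs is not None:
        est.ci = (jitter_value(est.ci[0], est.ci_strs[0], rng),
                  jitter_value(est.ci[1], est.ci_strs[1], rng))
    if est.p is not None and est.p_str is not None:
        est.p = max(jitter_value(est.p, "0" + est.p_str.lstrip("0"), rng), 1e-12)
    return est
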