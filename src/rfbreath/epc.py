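"""EPC encoding of subject identity and tag placement.

UHF Gen2 tags carry a rewritable EPC whose memory is word (16-bit)
addressable.  We reserve the trailing word to bind each tag to the person
and body part it monitors: the high 12 bits hold the subject id, the low
nibble a body-part code.  Decoding this word recovers the
``EPC -> (subject_id, body_part)`` mapping without any side channel; an
explicit subject-map file can always override it.
"""
from __future__ import annotations

from .errors import InvalidArgumentError, UnmappedTagError

#: Body parts a tag can be deployed on (chest listed first; it is the
#: preferred tag when both of a subject's tags are informative).
BODY_PARTS = ("chest", "abdomen")

_BP_CODE = {"chest": 0x1, "abdomen": 0x2}
_CODE_BP = {v: k for k, v in _BP_CODE.items()}

#: Default 80-bit EPC prefix; the trailing 16-bit word carries (id, bp).
DEFAULT_EPC_PREFIX = "E2806894000000000000"

MAX_SUBJECT_ID = 0xFFF  # 12 bits


def encode_epc(subject_id: int, body_part: str, prefix: str = DEFAULT_EPC_PREFIX) -> str:
    """Append the ``[id:12][bp:4]`` word to *prefix* and return the EPC hex string."""
    if not 0 <= subject_id <= MAX_SUBJECT_ID:
        raise InvalidArgumentError(
            f"subject_id {subject_id} does not fit in 12 bits")
    if body_part not in _BP_CODE:
        raise InvalidArgumentError(
            f"body_part must be one of {BODY_PARTS}, got {body_part!r}")
    if len(prefix) % 4 != 0:
        raise InvalidArgumentError("EPC prefix must be a whole number of 16-bit words")
    word = (subject_id << 4) | _BP_CODE[body_part]
    return f"{prefix}{word:04X}"


def decode_epc(epc: str) -> tuple[int, str]:
    """Recover ``(subject_id, body_part)`` from the trailing EPC word.

    Raises :class:`UnmappedTagError` when the trailing word does not carry a
    valid body-part code (i.e. the tag was never programmed for monitoring).
    """
    if len(epc) < 4:
        raise UnmappedTagError(epc)
    try:
        word = int(epc[-4:], 16)
    except ValueError:
        raise UnmappedTagError(epc) from None
    bp_code = word & 0xF
    if bp_code not in _CODE_BP:
        raise UnmappedTagError(epc)
    return word >> 4, _CODE_BP[bp_code]
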