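"""NHS number generation and modulus-11 validation.

An NHS number is ten digits: nine identifying digits plus a check digit
computed with the national modulus-11 scheme. Digits 1-9 are weighted
10..2, summed, and the remainder of division by 11 subtracted from 11
gives the check digit; a result of 11 maps to 0 and a result of 10 is
not a valid NHS number (such candidates are never issued).
"""

from __future__ import annotations

import numpy as np

_WEIGHTS = np.arange(10, 1, -1)  # 10..2 over the nine identifying digits


def nhs_check_digit(nine_digits: str) -> int | None:
    """Check digit for a 9-digit stem, or None when the stem is uncheckable."""
    if len(nine_digits) != 9 or not nine_digits.isdigit():
        return None
    total = sum(int(d) * w for d, w in zip(nine_digits, _WEIGHTS))
    check = 11 - (total % 11)
    if check == 11:
        return 0
    if check == 10:
        return None
    return check


def is_valid_nhs_number(number: str) -> bool:
    if not isinstance(number, str) or len(number) != 10 or not number.isdigit():
        return False
    return nhs_check_digit(number[:9]) == int(number[9])


def generate_nhs_numbers(n: int, rng: np.random.Generator) -> list[str]:
    """Draw ``n`` distinct, check-digit-valid NHS numbers."""
    if n < 0:
        raise ValueError("n must be non-negative")
    numbers: set[str] = set()
    while len(numbers) < n:
        need = n - len(numbers)
        stems = rng.integers(100_000_000, 1_000_000_000, size=int(need * 1.2) + 8)
        digits = np.array([list(map(int, str(s))) for s in stems])
        totals = digits @ _WEIGHTS
        checks = 11 - (totals % 11)
        checks[checks == 11] = 0
        ok = checks != 10
        for stem, check in zip(stems[ok], checks[ok]):
            numbers.add(f"{stem}{check}")
            if len(numbers) == n:
                break
    return sorted(numbers)
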