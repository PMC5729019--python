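"""Role-based visibility and working-group patient scoping.

Two orthogonal axes control what a user can see:

* **Working groups** partition the cohort jurisdictionally (clinic, state,
  country).  A user reaches exactly the patients whose working groups
  intersect their own — with *no* admin bypass, since patient reach is a
  privacy boundary, not a convenience.
* **User groups** are roles (clinical, genetic, curator, admin, patient)
  that the permission matrix maps to form, field and report visibility.
  The ``admin`` role bypasses form/field/report restrictions.  Anything
  missing from the matrix is deny-by-default.

Authentication is out of scope: the engine trusts an injected ``User``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

from .base import AccessDeniedError, IrdrError, UnknownCodeError

ADMIN_GROUP = "admin"


@dataclass(frozen=True)
class User:
    username: str
    user_groups: frozenset[str]
    working_groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.user_groups:
            raise IrdrError(f"user {self.username!r} has no user group")

    @property
    def is_admin(self) -> bool:
        return ADMIN_GROUP in self.user_groups


def make_user(username: str, user_groups: Iterable[str],
              working_groups: Iterable[str] = ()) -> User:
    return User(username, frozenset(user_groups), frozenset(working_groups))


@dataclass
class PermissionMatrix:
    """form code → allowed user groups; optional per-DE overrides; report
    template name → allowed user groups.  DEs without an override inherit
    their form's visibility."""

    form_visibility: dict[str, set[str]] = field(default_factory=dict)
    de_visibility: dict[str, set[str]] = field(default_factory=dict)
    report_access: dict[str, set[str]] = field(default_factory=dict)


def accessible_patients(user: User, patients: Sequence[Any]) -> list[Any]:
    """Patients whose working groups intersect the user's (order kept).

    Deliberately no admin exception: jurisdictional reach is always scoped.
    """
    return [p for p in patients
            if set(p.working_groups) & set(user.working_groups)]


def visible_forms(user: User, defn: Any) -> list[Any]:
    """Forms whose visibility set intersects the user's groups; admins see
    all; a form absent from the matrix (or with an empty set) is hidden from
    every non-admin."""
    matrix: PermissionMatrix = defn.permission_matrix
    if user.is_admin:
        return list(defn.forms)
    return [f for f in defn.forms
            if matrix.form_visibility.get(f.code, set()) & set(user.user_groups)]


def visible_des(user: User, form: Any, matrix: PermissionMatrix) -> list[str]:
    """DE codes of ``form`` the user may see, in form order.

    A DE with an entry in ``de_visibility`` uses that set; others inherit
    the form's visibility (already established by the caller seeing the
    form).  Admins see every DE.
    """
    form_groups = matrix.form_visibility.get(form.code, set())
    if not user.is_admin and not (form_groups & set(user.user_groups)):
        raise AccessDeniedError(
            f"user {user.username!r} cannot see form {form.code!r}")
    out: list[str] = []
    for section in form.sections:
        for de_code in section.de_codes:
            if de_code in out:
                continue
            if user.is_admin:
                out.append(de_code)
                continue
            allowed = matrix.de_visibility.get(de_code)
            if allowed is None or (allowed & set(user.user_groups)):
                out.append(de_code)
    return out


def authorize_report(user: User, template_name: str,
                     matrix: PermissionMatrix) -> bool:
    """True iff the user's groups intersect the template's access set, or
    the user is admin.  An empty access set is admin-only."""
    if template_name not in matrix.report_access:
        raise UnknownCodeError(f"unknown report template {template_name!r}")
    if user.is_admin:
        return True
    return bool(matrix.report_access[template_name] & set(user.user_groups))
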