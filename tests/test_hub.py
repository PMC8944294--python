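"""Online operations against the local repository emulator."""

import logging

import openpyxl
import pytest

from sbolbatch import fixtures
from sbolbatch.edit import clean_document
from sbolbatch.hub import (
    CredentialError,
    RetryPolicy,
    TransportError,
    collection_to_table,
    deposit_folder,
    login,
    update_records,
)
from sbolbatch.sbolio import write_sbol
from sbolbatch.tableio import read_table
from sbolbatch.mockhub import MockSynBioHub

FAST = RetryPolicy(max_attempts=3, backoff=(0.01, 0.02))


def _deposit_dir(tmp_path, n=3, name="dep"):
    folder = tmp_path / name
    folder.mkdir()
    for i in range(n):
        doc = clean_document(fixtures.make_dirty_document(1, seed=100 + i),
                             target_prefix=fixtures.DEFAULT_PREFIX)
        doc.components[0].display_id = f"design_{name}_{i}"
        doc.reindex()
        write_sbol(doc, folder / f"design_{i}.xml")
    return folder


# -- login ------------------------------------------------------------------

def test_login_returns_session_token(mock_hub):
    session = login(mock_hub.base_url, "demo", "secret")
    assert session.token == "token-demo"


def test_wrong_password_is_credential_error(mock_hub):
    with pytest.raises(CredentialError, match="demo"):
        login(mock_hub.base_url, "demo", "wrong")


def test_unreachable_host_is_transport_error_naming_host():
    with pytest.raises(TransportError, match="127.0.0.1:9"):
        login("http://127.0.0.1:9", "demo", "secret")


def test_password_never_logged(mock_hub, caplog):
    with caplog.at_level(logging.DEBUG):
        login(mock_hub.base_url, "demo", "secret")
    assert "secret" not in caplog.text


# -- deposit ----------------------------------------------------------------

def test_deposit_issues_one_submission_per_file(mock_hub, hub_session, tmp_path):
    folder = _deposit_dir(tmp_path, n=3)
    report = deposit_folder(hub_session, [folder])
    assert [i.outcome for i in report.items] == ["ok"] * 3
    submits = [r for r in mock_hub.requests if r.path == "/submit"]
    assert len(submits) == 3


def test_empty_folder_issues_no_requests(mock_hub, hub_session, tmp_path):
    folder = tmp_path / "empty"
    folder.mkdir()
    report = deposit_folder(hub_session, [folder])
    assert report.items == []
    assert [r for r in mock_hub.requests if r.path == "/submit"] == []


def test_dropped_connection_retried_once_then_ok(mock_hub, hub_session, tmp_path):
    folder = _deposit_dir(tmp_path, n=1)
    mock_hub.inject_fault("/submit", kind="drop", times=1)
    report = deposit_folder(hub_session, [folder])
    assert report.items[0].outcome == "ok"
    assert report.items[0].attempts == 2


def test_server_errors_exhaust_retry_budget(mock_hub, hub_session, tmp_path):
    folder = _deposit_dir(tmp_path, n=1)
    mock_hub.inject_fault("/submit", kind="503", times=10)
    report = deposit_folder(hub_session, [folder])
    assert report.items[0].outcome == "failed"
    submits = [r for r in mock_hub.requests if r.path == "/submit"]
    assert len(submits) == FAST.max_attempts


def test_conflict_without_overwrite_is_skipped(mock_hub, hub_session, tmp_path):
    folder = _deposit_dir(tmp_path, n=1)
    assert deposit_folder(hub_session, [folder]).items[0].outcome == "ok"
    report = deposit_folder(hub_session, [folder])
    assert report.items[0].outcome == "skipped"
    report = deposit_folder(hub_session, [folder], overwrite=True)
    assert report.items[0].outcome == "ok"


def test_batch_report_csv(tmp_path, mock_hub, hub_session):
    folder = _deposit_dir(tmp_path, n=2)
    report = deposit_folder(hub_session, [folder])
    csv_path = report.write_csv(tmp_path / "report.csv")
    lines = csv_path.read_text().strip().splitlines()
    assert lines[0] == "item,action,attempts,outcome,message"
    assert len(lines) == 3


# -- update / synbio2table --------------------------------------------------

def _seed_members(mock_hub, hub_session, tmp_path, n=3):
    deposit_folder(hub_session, [_deposit_dir(tmp_path, n=n, name="seeded")])
    return sorted(mock_hub.members)


def test_update_touches_only_listed_members(mock_hub, hub_session, tmp_path):
    members = _seed_members(mock_hub, hub_session, tmp_path, n=3)
    table_path = tmp_path / "update.xlsx"
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append(["display_id", "notes"])
    ws.append([members[0], "verified"])
    wb.save(table_path)
    mock_hub.requests.clear()
    report = update_records(hub_session, read_table(table_path))
    assert [i.outcome for i in report.items] == ["ok"]
    edits = [r for r in mock_hub.requests if r.path.endswith("/edit")]
    assert len(edits) == 1
    assert members[0] in edits[0].path
    assert edits[0].fields == {"field": "notes", "value": "verified"}
    assert mock_hub.members[members[0]]["notes"] == "verified"
    assert mock_hub.members[members[1]]["notes"] == ""


def test_update_unknown_display_id_fails_row_but_continues(
        mock_hub, hub_session, tmp_path):
    members = _seed_members(mock_hub, hub_session, tmp_path, n=1)
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append(["display_id", "notes"])
    ws.append(["ghost", "x"])
    ws.append([members[0], "real"])
    path = tmp_path / "u.xlsx"
    wb.save(path)
    report = update_records(hub_session, read_table(path))
    outcomes = {i.item: i.outcome for i in report.items}
    assert outcomes == {"ghost": "failed", members[0]: "ok"}


def test_update_uploads_attachment_as_multipart(mock_hub, hub_session, tmp_path):
    members = _seed_members(mock_hub, hub_session, tmp_path, n=1)
    attachment = tmp_path / "trace.ab1.txt"
    attachment.write_text("sequencing trace data")
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append(["display_id", "attachment"])
    ws.append([members[0], str(attachment)])
    path = tmp_path / "u.xlsx"
    wb.save(path)
    report = update_records(hub_session, read_table(path))
    assert report.items[0].outcome == "ok"
    attaches = [r for r in mock_hub.requests if r.path.endswith("/attach")]
    assert len(attaches) == 1
    (name, filename, content) = attaches[0].files[0]
    assert filename == "trace.ab1.txt"
    assert content == b"sequencing trace data"
    assert mock_hub.attachments[members[0]] == ["trace.ab1.txt"]


def test_missing_attachment_file_fails_row(mock_hub, hub_session, tmp_path):
    members = _seed_members(mock_hub, hub_session, tmp_path, n=1)
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append(["display_id", "attachment"])
    ws.append([members[0], str(tmp_path / "nope.ab1")])
    path = tmp_path / "u.xlsx"
    wb.save(path)
    report = update_records(hub_session, read_table(path))
    assert report.items[0].outcome == "failed"
    assert "nope.ab1" in report.items[0].message


def test_collection_export_fill_update_round_trip(mock_hub, hub_session, tmp_path):
    members = _seed_members(mock_hub, hub_session, tmp_path, n=2)
    out = collection_to_table(hub_session, tmp_path / "members.xlsx")
    table = read_table(out)
    assert [r.display_id for r in table] == members
    for heading in ("display_id", "name", "description", "notes", "attachment"):
        assert heading in table.columns
    # fill notes and push back
    wb = openpyxl.load_workbook(out)
    ws = wb.active
    headers = [c.value for c in ws[1]]
    col = headers.index("notes") + 1
    for r in range(2, ws.max_row + 1):
        ws.cell(row=r, column=col, value="stage 3: verified")
    filled = tmp_path / "filled.xlsx"
    wb.save(filled)
    update_records(hub_session, read_table(filled))
    again = read_table(collection_to_table(hub_session, tmp_path / "again.xlsx"))
    # exported table reflects the server state after the update
    assert {m["notes"] for m in mock_hub.members.values()} == {"stage 3: verified"}
    assert [r.display_id for r in again] == members
    assert [r.values["notes"] for r in again] == ["stage 3: verified"] * 2
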