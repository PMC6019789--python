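"""Job planning, the worker pool, result sinks, and performance metrics.

A job is a filter condition plus the set of BAM files to apply it to; it
is decomposed into one task per file.  Workers are plain threads pulling
from a single shared queue — the contract preserved from the distributed
original is "one queue, tasks pulled on availability", so the merged
output multiset is independent of worker count and scheduling order.
Task failures are isolated and recorded; they never suppress sibling
outputs.
"""

from __future__ import annotations

import queue
import tempfile
import threading
import time
import uuid
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .alignment_io import (
    DataSource,
    Manifest,
    read_header,
    stream_alignments,
    write_bam,
    write_iaf,
)
from .errors import (
    SourceUnavailableError,
    UnknownJobError,
    ValidationError,
)
from .filters import FilterSpec, in_regions, matches_filter

PENDING, RUNNING, DONE, FAILED = "pending", "running", "done", "failed"
_TERMINAL = (DONE, FAILED)


@dataclass
class Job:
    """A filter condition and the files to apply it to."""

    job_id: str
    spec: FilterSpec
    files: list[tuple[DataSource, str]]  # (source, individual_id)
    output_format: str = "iaf"  # iaf | bam
    sink: Optional["LocalDirectorySink"] = None

    def __post_init__(self):
        if not self.files:
            raise ValidationError("job has no files")
        ids = [ind for _, ind in self.files]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate individual ids within a job")
        if self.output_format not in ("iaf", "bam"):
            raise ValidationError(f"unknown output format {self.output_format!r}")


@dataclass
class Task:
    """One unit of dispatch: a single BAM file under a job's filter."""

    task_id: str
    job_id: str
    source: DataSource
    individual_id: str
    state: str = PENDING
    records_in: int = 0
    records_out: int = 0
    bytes_streamed: int = 0
    wall_seconds: float = 0.0
    error: Optional[str] = None
    locator: Optional[str] = None

    def result(self) -> "TaskResult":
        return TaskResult(
            task_id=self.task_id,
            job_id=self.job_id,
            individual_id=self.individual_id,
            state=self.state,
            records_in=self.records_in,
            records_out=self.records_out,
            bytes_streamed=self.bytes_streamed,
            wall_seconds=self.wall_seconds,
            error=self.error,
            locator=self.locator,
        )


@dataclass(frozen=True)
class TaskResult:
    task_id: str
    job_id: str
    individual_id: str
    state: str
    records_in: int
    records_out: int
    bytes_streamed: int
    wall_seconds: float
    error: Optional[str] = None
    locator: Optional[str] = None


@dataclass(frozen=True)
class JobStatus:
    job_id: str
    counts: dict[str, int]
    tasks: tuple[TaskResult, ...]

    @property
    def finished(self) -> bool:
        return self.counts[PENDING] == 0 and self.counts[RUNNING] == 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


class LocalDirectorySink:
    """Two-method, stateless sink contract over a local directory.

    ``put`` stores a named byte payload and returns a locator; ``get``
    resolves a locator back to bytes.  Jobs namespace their outputs by
    job id, so two jobs can share a sink without colliding.
    """

    def __init__(self, root: Union[str, Path]):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def put(self, name: str, data: bytes) -> str:
        path = self.root / name
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_bytes(data)
        return str(path)

    def get(self, locator: str) -> bytes:
        return Path(locator).read_bytes()


class FilterEngine:
    """Plans jobs into tasks, runs them on a thread pool, tracks status."""

    def __init__(self, manifest: Optional[Manifest] = None):
        self.manifest = manifest
        self._jobs: dict[str, Job] = {}
        self._tasks: dict[str, list[Task]] = {}
        self._lock = threading.Lock()

    # -- planning --------------------------------------------------------
    def plan_job(self, job: Job) -> list[Task]:
        """One pending task per file, in file order.

        Cohort criteria (samples/populations in the spec) are applied
        here: files whose individual falls outside the subset get no
        task.  Population resolution needs a manifest.
        """
        files = job.files
        spec = job.spec
        if spec.samples or spec.populations:
            if spec.populations and self.manifest is None:
                raise ValidationError("population subsetting requires a manifest")
            if self.manifest is not None:
                chosen = self.manifest.subset(spec.samples, spec.populations)
            else:
                chosen = set(spec.samples)
            files = [(src, ind) for src, ind in files if ind in chosen]
            if not files:
                raise ValidationError("cohort subset matches no files in the job")
        tasks = [
            Task(
                task_id=f"{job.job_id}.{i:05d}",
                job_id=job.job_id,
                source=src,
                individual_id=ind,
            )
            for i, (src, ind) in enumerate(files)
        ]
        with self._lock:
            self._jobs[job.job_id] = job
            self._tasks[job.job_id] = tasks
        return tasks

    # -- execution -------------------------------------------------------
    def run_job(self, job: Job, workers: int = 1) -> list[TaskResult]:
        """Run all tasks of a job on ``workers`` threads sharing one queue."""
        if workers < 1:
            raise ValidationError("workers must be >= 1")
        if job.job_id not in self._tasks:
            self.plan_job(job)
        tasks = self._tasks[job.job_id]
        q: queue.Queue[Task] = queue.Queue()
        for t in tasks:
            q.put(t)

        def worker():
            while True:
                try:
                    task = q.get_nowait()
                except queue.Empty:
                    return
                try:
                    self._execute_task(job, task)
                finally:
                    q.task_done()

        threads = [threading.Thread(target=worker) for _ in range(workers)]
        for th in threads:
            th.start()
        for th in threads:
            th.join()
        return [t.result() for t in tasks]

    def _execute_task(self, job: Job, task: Task) -> None:
        with self._lock:
            task.state = RUNNING
        t0 = time.monotonic()
        try:
            records = self._filter_one(job, task, retry=True)
            locator = self._emit(job, task, records)
            with self._lock:
                task.locator = locator
                task.wall_seconds = time.monotonic() - t0
                task.state = DONE
        except Exception as exc:  # isolate the failure to this task
            with self._lock:
                task.error = f"{type(exc).__name__}: {exc}"
                task.wall_seconds = time.monotonic() - t0
                task.state = FAILED

    def _filter_one(self, job: Job, task: Task, retry: bool) -> list:
        spec = job.spec
        use_fetch = bool(spec.regions) and task.source.supports_random_access
        regions = spec.regions if use_fetch else ()
        try:
            out = []
            n_in = 0
            for rec in stream_alignments(task.source, regions):
                n_in += 1
                if matches_filter(rec, spec):
                    out.append(rec)
            task.records_in = n_in
            task.records_out = len(out)
            task.bytes_streamed = task.source.size_bytes()
            return out
        except SourceUnavailableError:
            if retry:  # one automatic retry on retryable I/O errors
                return self._filter_one(job, task, retry=False)
            raise

    def _emit(self, job: Job, task: Task, records: list) -> str:
        sink = job.sink
        name = f"{job.job_id}/{task.individual_id}.{job.output_format}"
        with tempfile.TemporaryDirectory() as tmp:
            tmp_path = Path(tmp) / "out"
            if job.output_format == "iaf":
                write_iaf(records, task.individual_id, job.spec.region_label(), tmp_path)
            else:
                header = read_header(task.source)
                write_bam(records, header, tmp_path)
            data = tmp_path.read_bytes()
        if sink is None:
            raise ValidationError(f"job {job.job_id} has no sink")
        return sink.put(name, data)

    # -- monitoring ------------------------------------------------------
    def job_status(self, job_id: str) -> JobStatus:
        with self._lock:
            if job_id not in self._tasks:
                raise UnknownJobError(job_id)
            tasks = tuple(t.result() for t in self._tasks[job_id])
        counts = {s: 0 for s in (PENDING, RUNNING, DONE, FAILED)}
        for t in tasks:
            counts[t.state] += 1
        return JobStatus(job_id=job_id, counts=counts, tasks=tasks)

    def collect_results(self, job_id: str) -> list[str]:
        """Locators of all finished tasks; failed tasks are simply absent."""
        status = self.job_status(job_id)
        return [t.locator for t in status.tasks if t.state == DONE and t.locator]


def new_job_id() -> str:
    return uuid.uuid4().hex[:12]


# ---------------------------------------------------------------------------
# Performance metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunTiming:
    """Wall time for a whole job at a given worker count."""

    n: int
    wall_seconds: float

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("worker count must be >= 1")
        if self.wall_seconds <= 0:
            raise ValidationError("wall time must be positive")


def throughput(results: Sequence[TaskResult], wall_seconds_total: float) -> float:
    """Streamed-and-filtered bytes per second of total wall time."""
    if wall_seconds_total <= 0:
        raise ValidationError("wall time must be positive")
    return sum(r.bytes_streamed for r in results) / wall_seconds_total


def scaled_speedup(timings: Sequence[RunTiming]) -> dict[int, float]:
    """Per worker count n: (T_1 / T_n) / n; 1.0 marks linear scaling."""
    by_n = {t.n: t.wall_seconds for t in timings}
    if 1 not in by_n:
        raise ValidationError("scaled speedup needs the n=1 baseline timing")
    t1 = by_n[1]
    return {n: (t1 / tn) / n for n, tn in sorted(by_n.items())}
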