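"""nodulecam: lightweight 3D CNN lung-nodule classification with Grad-CAM.

The package reconstructs three published nodule-classifier architectures
from their layer tables, audits the reconstruction against the printed
parameter counts, trains the networks on synthetic nodule phantoms with
voxel-level ground truth, evaluates them with standard confusion-matrix
and ROC statistics, and explains their decisions with gradient-weighted
class activation maps.
"""

from .architectures import (
    AuditReport,
    ExpectedCount,
    LayerSpec,
    ModelHandle,
    NetworkDescription,
    audit,
    build_model,
    canonical_description,
    count_parameters,
    derive_kernel_size,
    load_description,
    save_description,
)
from .evaluation import (
    ConfusionCounts,
    MetricsReport,
    confusion,
    evaluate_predictions,
    metrics,
    roc_auc,
)
from .gradcam import (
    GradCamContext,
    Heatmap,
    class_weights,
    global_average_pool,
    grad_cam,
    overlay,
)
from .io import VolumeRecord, read_manifest, read_volume, write_manifest, write_volume
from .phantom import (
    PhantomConfig,
    PhantomSample,
    SplitManifest,
    easy_config,
    generate_dataset,
    generate_sample,
    make_splits,
)
from .training import (
    ClassifierResults,
    NoduleClassifier,
    TrainConfig,
    TrainHistory,
    cross_entropy_loss,
    predict,
    softmax,
    train,
)

__version__ = "0.1.0"
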