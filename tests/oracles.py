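"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain-python loops, independent
of the package's numpy/sklearn code paths.
"""

from __future__ import annotations


def brute_binary_metrics(y_true, probs, threshold=0.5):
    pred = [1 if p >= threshold else 0 for p in probs]
    tp = sum(1.0 for a, b in zip(pred, y_true) if a == 1 and b == 1)
    fp = sum(1.0 for a, b in zip(pred, y_true) if a == 1 and b == 0)
    fn = sum(1.0 for a, b in zip(pred, y_true) if a == 0 and b == 1)
    tn = sum(1.0 for a, b in zip(pred, y_true) if a == 0 and b == 0)
    n = len(y_true)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return {
        "accuracy": (tp + tn) / n if n else 0.0,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "roc_auc": brute_roc_auc(y_true, probs),
    }


def brute_roc_auc(y_true, probs):
    """Pairwise (Mann-Whitney) statistic with ties counted as 1/2."""
    pos = [p for p, y in zip(probs, y_true) if y == 1]
    neg = [p for p, y in zip(probs, y_true) if y == 0]
    if not pos or not neg:
        return None
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_topk_sets(prob_row, k):
    """Indices of the k highest scores, ties toward the lower index."""
    order = sorted(range(len(prob_row)), key=lambda j: (-prob_row[j], j))
    return set(order[:k])


def brute_multilabel_metrics(Y, P, threshold=0.5, k=10, topk_mode="all"):
    n = len(Y)
    n_labels = len(Y[0]) if n else 0
    k = min(k, n_labels)
    pred = [[1 if P[i][j] >= threshold else 0 for j in range(n_labels)]
            for i in range(n)]

    def macro(prediction):
        ps, rs, fs = [], [], []
        for j in range(n_labels):
            tp = sum(1.0 for i in range(n)
                     if prediction[i][j] == 1 and Y[i][j] == 1)
            fp = sum(1.0 for i in range(n)
                     if prediction[i][j] == 1 and Y[i][j] == 0)
            fn = sum(1.0 for i in range(n)
                     if prediction[i][j] == 0 and Y[i][j] == 1)
            p_j = tp / (tp + fp) if (tp + fp) > 0 else 0.0
            r_j = tp / (tp + fn) if (tp + fn) > 0 else 0.0
            f_j = 2 * p_j * r_j / (p_j + r_j) if (p_j + r_j) > 0 else 0.0
            ps.append(p_j)
            rs.append(r_j)
            fs.append(f_j)
        m = n_labels if n_labels else 1
        return sum(ps) / m, sum(rs) / m, sum(fs) / m

    macro_p, macro_r, macro_f = macro(pred)
    accuracy = (sum(1.0 for i in range(n) if pred[i] == list(Y[i])) / n
                if n else 0.0)

    hits = 0.0
    topk_pred = []
    for i in range(n):
        top = brute_topk_sets(P[i], k)
        true = {j for j in range(n_labels) if Y[i][j] == 1}
        if topk_mode == "all":
            hits += 1.0 if true <= top else 0.0
        else:
            hits += 1.0 if (true & top or not true) else 0.0
        topk_pred.append([1 if j in top else 0 for j in range(n_labels)])
    tp_p, tp_r, tp_f = macro(topk_pred)
    return {
        "accuracy": accuracy,
        "macro_precision": macro_p, "macro_recall": macro_r, "macro_f1": macro_f,
        "topk_accuracy": hits / n if n else 0.0,
        "topk_macro_precision": tp_p, "topk_macro_recall": tp_r,
        "topk_macro_f1": tp_f,
    }
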