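<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>chemspace3d scene viewer</title>
<style>
  html, body { margin: 0; height: 100%; background: #111; color: #ddd;
               font-family: sans-serif; overflow: hidden; }
  #hud { position: absolute; top: 8px; left: 8px; background: rgba(0,0,0,.65);
         padding: 6px 10px; border-radius: 4px; font-size: 13px;
         max-width: 40em; pointer-events: none; }
  canvas { display: block; }
</style>
</head>
<body>
<div id="hud">drag to rotate, wheel to zoom, hover a point for details</div>
<canvas id="view"></canvas>
<script type="application/json" id="scene-data">/*__SCENE_JSON__*/</script>
<script>
"use strict";
var scene = JSON.parse(document.getElementById("scene-data").textContent);
var canvas = document.getElementById("view");
var ctx = canvas.getContext("2d");
var hud = document.getElementById("hud");

var pts = [];
scene.points.forEach(function (p) {
  pts.push({cell: p.cell, rgb: p.rgb,
            label: p.member_ids.join(", ") + " | " + p.representative_smiles});
});
scene.overlay_points.forEach(function (p) {
  pts.push({cell: p.cell, rgb: p.rgb, label: "[external] " + p.id + " " + p.name});
});

var half = scene.n_bins / 2;
var rotX = 0.5, rotY = 0.6, zoom = 1.2, dragging = false, lastX = 0, lastY = 0;
var projected = [];

function draw() {
  var w = canvas.width = window.innerWidth;
  var h = canvas.height = window.innerHeight;
  ctx.fillStyle = "#111";
  ctx.fillRect(0, 0, w, h);
  var scale = zoom * Math.min(w, h) / (scene.n_bins * 1.6);
  var cx = Math.cos(rotX), sx = Math.sin(rotX);
  var cy = Math.cos(rotY), sy = Math.sin(rotY);
  projected = [];
  pts.forEach(function (p) {
    var x = p.cell[0] - half, y = p.cell[1] - half, z = p.cell[2] - half;
    var x1 = cy * x + sy * z, z1 = -sy * x + cy * z;
    var y1 = cx * y - sx * z1, z2 = sx * y + cx * z1;
    var sxp = w / 2 + x1 * scale, syp = h / 2 - y1 * scale;
    var r = Math.max(1.5, 4 - z2 / half * 2);
    projected.push({x: sxp, y: syp, r: r, p: p, depth: z2});
  });
  projected.sort(function (a, b) { return a.depth - b.depth; });
  projected.forEach(function (q) {
    ctx.fillStyle = "rgb(" + q.p.rgb.join(",") + ")";
    ctx.beginPath();
    ctx.arc(q.x, q.y, q.r, 0, 2 * Math.PI);
    ctx.fill();
  });
}

canvas.addEventListener("mousedown", function (e) {
  dragging = true; lastX = e.clientX; lastY = e.clientY;
});
window.addEventListener("mouseup", function () { dragging = false; });
window.addEventListener("mousemove", function (e) {
  if (dragging) {
    rotY += (e.clientX - lastX) * 0.01;
    rotX += (e.clientY - lastY) * 0.01;
    lastX = e.clientX; lastY = e.clientY;
    draw();
    return;
  }
  var best = null, bestD = 64;
  projected.forEach(function (q) {
    var dx = q.x - e.clientX, dy = q.y - e.clientY;
    var d = dx * dx + dy * dy;
    if (d < bestD) { bestD = d; best = q; }
  });
  hud.textContent = best ? best.p.label
    : scene.fingerprint_kind + " space, colored by " + scene.descriptor +
      " (" + pts.length + " points)";
});
canvas.addEventListener("wheel", function (e) {
  zoom *= e.deltaY < 0 ? 1.1 : 0.9;
  draw();
  e.preventDefault();
});
window.addEventListener("resize", draw);
draw();
</script>
</body>
</html>
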