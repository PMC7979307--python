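name: alexnet3d
input_shape:
- 1
- 32
- 32
- 32
layers:
- kind: conv3d
  in_channels: 1
  out_channels: 16
  activation: relu
  bias: true
  kernel: 8
  stride: 1
  padding: same
  printed_params: 8208
- kind: batchnorm
  out_channels: 16
  printed_params: 64
- kind: maxpool3d
  kernel: 2
  stride: 2
  printed_params: 0
- kind: conv3d
  in_channels: 16
  out_channels: 32
  activation: relu
  bias: true
  kernel: 3
  stride: 1
  padding: same
  printed_params: 13856
- kind: batchnorm
  out_channels: 32
  printed_params: 128
- kind: maxpool3d
  kernel: 2
  stride: 2
  printed_params: 0
- kind: conv3d
  in_channels: 32
  out_channels: 64
  activation: relu
  bias: true
  kernel: 3
  stride: 1
  padding: same
  printed_params: 55360
- kind: batchnorm
  out_channels: 64
  printed_params: 256
- kind: conv3d
  in_channels: 64
  out_channels: 64
  activation: relu
  bias: true
  kernel: 3
  stride: 1
  padding: same
  printed_params: 110656
- kind: batchnorm
  out_channels: 64
  printed_params: 256
- kind: conv3d
  in_channels: 64
  out_channels: 32
  activation: relu
  bias: true
  kernel: 3
  stride: 1
  padding: same
  printed_params: 53328
  known_typo: true
  corrected_params: 55328
- kind: batchnorm
  out_channels: 32
  printed_params: 128
- kind: maxpool3d
  kernel: 2
  stride: 2
  printed_params: 0
- kind: flatten
  printed_params: 0
- kind: dense
  in_channels: 2048
  out_channels: 200
  activation: relu
  bias: true
  printed_params: 409800
- kind: batchnorm
  out_channels: 200
  printed_params: 800
- kind: dropout
  dropout_rate: 0.5
  printed_params: 0
- kind: dense
  in_channels: 200
  out_channels: 75
  activation: relu
  bias: true
  printed_params: 15075
- kind: batchnorm
  out_channels: 75
  printed_params: 300
- kind: dropout
  dropout_rate: 0.5
  printed_params: 0
- kind: dense
  in_channels: 75
  out_channels: 2
  activation: none
  bias: true
  printed_params: 152
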