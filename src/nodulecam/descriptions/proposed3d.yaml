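name: proposed3d
input_shape:
- 1
- 27
- 27
- 27
layers:
- kind: conv3d
  in_channels: 1
  out_channels: 16
  activation: relu
  bias: true
  kernel: 6
  stride: 1
  padding: same
  printed_params: 3472
- kind: batchnorm
  out_channels: 16
  printed_params: 64
- kind: conv3d
  in_channels: 16
  out_channels: 16
  activation: relu
  bias: true
  kernel: 2
  stride: 1
  padding: same
  printed_params: 2064
- kind: batchnorm
  out_channels: 16
  printed_params: 64
- kind: conv3d
  in_channels: 16
  out_channels: 16
  activation: relu
  bias: true
  kernel: 4
  stride: 1
  padding: valid
  printed_params: 16400
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
  kernel: 2
  stride: 1
  padding: valid
  printed_params: 4128
- kind: batchnorm
  out_channels: 32
  printed_params: 128
- kind: conv3d
  in_channels: 32
  out_channels: 32
  activation: relu
  bias: true
  kernel: 2
  stride: 1
  padding: valid
  printed_params: 8224
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
  kernel: 2
  stride: 1
  padding: valid
  printed_params: 16448
- kind: batchnorm
  out_channels: 64
  printed_params: 256
- kind: maxpool3d
  kernel: 4
  stride: 4
  printed_params: 0
- kind: flatten
  printed_params: 0
- kind: dense
  in_channels: 64
  out_channels: 256
  activation: relu
  bias: true
  printed_params: 16640
- kind: batchnorm
  out_channels: 256
  printed_params: 1024
- kind: dropout
  dropout_rate: 0.5
  printed_params: 0
- kind: dense
  in_channels: 256
  out_channels: 2
  activation: none
  bias: true
  printed_params: 514
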